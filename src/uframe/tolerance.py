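"""Automatic tolerance-size selection.

The tolerance size — the side of the square regions the image is split into
— controls where training sits between supervised (small regions) and
unsupervised (large regions) learning.  It is chosen by scanning candidate
sizes and maximizing, over random crop pairs, the Pearson correlation of
compressed feature descriptors of source and target crops: the assumption is
that at the right scale the two domains share feature patterns within a
region, so their descriptors co-vary.

The feature extractor is pluggable.  The default is a self-contained
descriptor (downsampled intensity grid + gradient-orientation histogram);
any callable with the same contract — fixed-length vector, deterministic,
size-independent — can be swapped in, e.g. an embedding from a pretrained
vision model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Protocol, runtime_checkable

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .errors import ContractError, InvalidGeometryError, MemoryFloorError

__all__ = [
    "pearson_correlation",
    "FeatureExtractor",
    "default_feature_descriptor",
    "ToleranceSearchConfig",
    "ToleranceResult",
    "optimize_tolerance",
]


def pearson_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation coefficient in [-1, 1].

    Returns 0.0 when either vector is constant (the coefficient is undefined
    there; see :func:`pearson_correlation_flagged` for the explicit flag).
    """
    r, _ = pearson_correlation_flagged(u, v)
    return r


def pearson_correlation_flagged(u: np.ndarray, v: np.ndarray) -> tuple[float, bool]:
    """As :func:`pearson_correlation`, plus a degeneracy flag."""
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    if u.shape != v.shape:
        raise ContractError(f"length mismatch: {u.size} vs {v.size}")
    if u.size < 2:
        raise ContractError("vectors must have length >= 2")
    su, sv = u.std(), v.std()
    if su == 0.0 or sv == 0.0:
        return 0.0, True
    r = float(np.mean((u - u.mean()) * (v - v.mean())) / (su * sv))
    return float(np.clip(r, -1.0, 1.0)), False


@runtime_checkable
class FeatureExtractor(Protocol):
    """Contract for pluggable patch descriptors.

    Must be deterministic and map a patch of any size (HxW or HxWxC) to a
    fixed-length 1-D float vector.
    """

    def __call__(self, patch: np.ndarray) -> np.ndarray: ...


_GRID = 8
_ORIENT_BINS = 16


def default_feature_descriptor(patch: np.ndarray) -> np.ndarray:
    """Built-in compressed feature representation of an image patch.

    Concatenates an 8x8 grid of mean gradient magnitude with a 16-bin axial
    (sign-folded) gradient-orientation histogram, both computed after
    collapsing channels.  Two properties matter for cross-domain comparison:

    * appearance robustness — gradient magnitude and axial orientation are
      unchanged by monotone intensity remappings, including contrast
      inversion, so corresponding structures correlate positively even when
      the two domains render them with opposite polarity;
    * fluctuation comparison — each block is standardised within itself
      (zero mean, unit variance), so the Pearson correlation of two
      descriptors compares their fluctuation patterns rather than the
      systematic offsets between blocks; without this, any two large
      featureless crops would correlate strongly simply because both
      resemble the global mean descriptor.

    Output length is fixed (64 + 16 = 80) for every patch size and channel
    count.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim == 3:
        patch = patch.mean(axis=-1)
    if patch.ndim != 2:
        raise ContractError(f"patch must be 2-D or 3-D, got ndim={patch.ndim}")
    if patch.shape[0] < _GRID or patch.shape[1] < _GRID:
        raise ContractError(f"patch {patch.shape} smaller than {_GRID}x{_GRID}")
    gy = ndimage.sobel(patch, axis=0, mode="reflect")
    gx = ndimage.sobel(patch, axis=1, mode="reflect")
    mag = np.hypot(gx, gy)
    grid = resize(mag, (_GRID, _GRID), anti_aliasing=True, mode="reflect")
    ang = np.mod(np.arctan2(gy, gx), np.pi)  # axial orientation in [0, pi)
    hist, _ = np.histogram(ang, bins=_ORIENT_BINS, range=(0.0, np.pi), weights=mag)

    def zscore(block: np.ndarray) -> np.ndarray:
        std = block.std()
        if std == 0:
            return np.zeros_like(block)
        return (block - block.mean()) / std

    return np.concatenate([zscore(grid.ravel()), zscore(hist)])


@dataclass(frozen=True)
class ToleranceSearchConfig:
    """Search-space and sampling settings for tolerance optimization.

    ``step_factor`` > 1 gives a multiplicative candidate schedule
    (lower, 2*lower, ... <= upper, upper); ``step_add`` instead walks an
    arithmetic grid.  ``head_cap`` is the memory floor: candidate tolerances
    whose region count N would push the discriminator head width N+1 above
    the cap are rejected at validation time.
    """

    lower_bound: int
    upper_bound: int
    num_sampling: int = 64
    step_factor: float | None = 2.0
    step_add: int | None = None
    feature_extractor: Callable[[np.ndarray], np.ndarray] = field(
        default=default_feature_descriptor
    )
    head_cap: int = 4096
    tie_band: float = 0.01
    matched_positions: bool = True
    seed: int = 0

    def candidates(self) -> list[int]:
        if self.lower_bound > self.upper_bound:
            raise ContractError("lower_bound must be <= upper_bound")
        if self.num_sampling < 1:
            raise ContractError("num_sampling must be >= 1")
        cands: list[int] = []
        if self.step_add is not None:
            cands = list(range(self.lower_bound, self.upper_bound + 1, self.step_add))
        else:
            f = self.step_factor or 2.0
            if f <= 1.0:
                raise ContractError("step_factor must be > 1")
            t = float(self.lower_bound)
            while round(t) <= self.upper_bound:
                cands.append(int(round(t)))
                t *= f
        if cands and cands[-1] != self.upper_bound:
            cands.append(self.upper_bound)
        return cands

    def validate_memory_floor(self, image_shape: tuple[int, int]) -> None:
        h, w = image_shape
        rows = -(-h // self.lower_bound)
        cols = -(-w // self.lower_bound)
        if rows * cols + 1 > self.head_cap:
            raise MemoryFloorError(
                f"lower_bound {self.lower_bound} yields {rows * cols} regions; "
                f"head width {rows * cols + 1} exceeds cap {self.head_cap} — "
                "raise the tolerance lower bound"
            )


@dataclass(frozen=True)
class ToleranceResult:
    tolerance: int
    candidates: tuple[int, ...]
    objective: tuple[float, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "tolerance": self.tolerance,
                "candidates": list(self.candidates),
                "objective": list(self.objective),
            }
        )


def _random_crop(image: np.ndarray, side: int, rng: np.random.Generator) -> np.ndarray:
    h, w = image.shape[:2]
    r = int(rng.integers(0, h - side + 1))
    c = int(rng.integers(0, w - side + 1))
    return image[r : r + side, c : c + side]


def optimize_tolerance(
    source: np.ndarray | list[np.ndarray],
    target: np.ndarray | list[np.ndarray],
    cfg: ToleranceSearchConfig,
) -> ToleranceResult:
    """Select the tolerance size maximizing summed descriptor correlation.

    For every candidate size, ``num_sampling`` source/target crop pairs are
    drawn at uniform positions, featurised, and their Pearson correlations
    summed.  By default the source and target crops of a draw share the same
    position (``matched_positions``): the objective then measures how
    *paired* the two domains are at that scale, which is the quantity the
    tolerance trades off.  With independent positions the objective reduces
    to a marginal-statistics comparison.  Candidates within ``tie_band``
    (relative) of the maximum form a tie band and the largest is returned —
    larger tolerance means fewer regions and a smaller discriminator head.
    """
    sources = source if isinstance(source, list) else [source]
    targets = target if isinstance(target, list) else [target]
    if len(sources) != len(targets):
        raise ContractError("source and target lists must have equal length")
    cands = cfg.candidates()
    min_side = min(min(im.shape[:2]) for im in sources + targets)
    if cfg.upper_bound > min_side:
        raise InvalidGeometryError(
            f"upper_bound {cfg.upper_bound} exceeds smallest image side {min_side}"
        )
    cfg.validate_memory_floor(sources[0].shape[:2])

    rng = np.random.default_rng(cfg.seed)
    extractor = cfg.feature_extractor
    objective = []
    any_defined = False
    for tol in cands:
        obj = 0.0
        for s_img, t_img in zip(sources, targets):
            for _ in range(cfg.num_sampling):
                if cfg.matched_positions:
                    h, w = s_img.shape[:2]
                    r = int(rng.integers(0, h - tol + 1))
                    c = int(rng.integers(0, w - tol + 1))
                    fs = extractor(s_img[r : r + tol, c : c + tol])
                    ft = extractor(t_img[r : r + tol, c : c + tol])
                else:
                    fs = extractor(_random_crop(s_img, tol, rng))
                    ft = extractor(_random_crop(t_img, tol, rng))
                r, degenerate = pearson_correlation_flagged(fs, ft)
                obj += r
                any_defined = any_defined or not degenerate
        objective.append(obj)
    if not any_defined:
        raise ContractError(
            "objective degenerate for every candidate (all correlations undefined)"
        )
    best = max(objective)
    band = abs(best) * cfg.tie_band
    chosen = max(t for t, o in zip(cands, objective) if o >= best - band)
    return ToleranceResult(
        tolerance=chosen, candidates=tuple(cands), objective=tuple(objective)
    )
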