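"""Region partition and the global patch-sampling rule.

An image is divided into mutually exclusive square regions of side
``tolerance`` (boundary regions truncated at the image edge), numbered in
row-major spatial order.  For patch cropping each region is expanded by an
``overlap`` margin so neighbouring regions partially share features.

Training patches are drawn region-first: region ``i`` is selected with
probability

    P_i = Q_i / sum_j Q_j,
    Q_i = (1 + corr(S_i, T_i)) / sum_j (H_i . H_j),

where ``corr`` is the Pearson correlation of the region's source and target
pixel vectors, and ``H_i`` is the region's normalised intensity histogram.
Well-correlated regions (roughly paired evidence) and rare regions (small
histogram overlap with the rest of the image) are both sampled more often.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, DegenerateDistributionError, InvalidGeometryError

__all__ = [
    "Rect",
    "RegionGrid",
    "SamplingDistribution",
    "partition_regions",
    "compute_sampling_distribution",
    "sample_patch_pair",
]


@dataclass(frozen=True)
class Rect:
    """Half-open axis-aligned rectangle: rows [r0, r1), cols [c0, c1)."""

    r0: int
    c0: int
    r1: int
    c1: int

    @property
    def height(self) -> int:
        return self.r1 - self.r0

    @property
    def width(self) -> int:
        return self.c1 - self.c0

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.r0, self.c0, self.r1, self.c1)


@dataclass(frozen=True)
class RegionGrid:
    """Partition of an image into tolerance-sized regions.

    ``regions[i]`` is the exclusive rectangle of region ``i`` (row-major
    order); ``expanded(i)`` grows it by ``overlap`` on each side, clipped to
    the image, and is the area patches may be cropped from.
    """

    image_shape: tuple[int, int]
    tolerance: int
    overlap: int
    regions: tuple[Rect, ...] = field(repr=False)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def expanded(self, index: int) -> Rect:
        r = self.regions[index]
        h, w = self.image_shape
        return Rect(
            max(0, r.r0 - self.overlap),
            max(0, r.c0 - self.overlap),
            min(h, r.r1 + self.overlap),
            min(w, r.c1 + self.overlap),
        )

    def region_of(self, row: int, col: int) -> int:
        """Index of the exclusive region containing pixel (row, col)."""
        ncols = -(-self.image_shape[1] // self.tolerance)
        return (row // self.tolerance) * ncols + (col // self.tolerance)

    def to_json(self) -> str:
        return json.dumps(
            {
                "image_shape": list(self.image_shape),
                "tolerance": self.tolerance,
                "overlap": self.overlap,
                "regions": [r.as_tuple() for r in self.regions],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RegionGrid":
        d = json.loads(text)
        return cls(
            image_shape=tuple(d["image_shape"]),
            tolerance=int(d["tolerance"]),
            overlap=int(d["overlap"]),
            regions=tuple(Rect(*r) for r in d["regions"]),
        )


@dataclass(frozen=True)
class SamplingDistribution:
    """Per-region histograms H, scores Q and selection probabilities P."""

    H: np.ndarray  # (N, B) rows sum to 1
    Q: np.ndarray  # (N,) nonnegative
    P: np.ndarray  # (N,) sums to 1

    def to_json(self) -> str:
        return json.dumps({"Q": self.Q.tolist(), "P": self.P.tolist()})


def partition_regions(
    image_shape: tuple[int, int],
    tolerance: int,
    overlap: int = 64,
    patch_size: int = 256,
) -> RegionGrid:
    """Divide an image into tolerance-sized mutually exclusive regions.

    Boundary regions are truncated at the image edge so that the regions
    cover the image exactly.  Raises :class:`InvalidGeometryError` if any
    expanded region cannot contain a ``patch_size`` square.
    """
    h, w = int(image_shape[0]), int(image_shape[1])
    if tolerance < 1:
        raise ContractError(f"tolerance must be >= 1, got {tolerance}")
    if overlap < 0:
        raise ContractError(f"overlap must be >= 0, got {overlap}")
    if h < tolerance or w < tolerance:
        raise InvalidGeometryError(
            f"image shape {(h, w)} smaller than tolerance {tolerance}"
        )
    rows = -(-h // tolerance)
    cols = -(-w // tolerance)
    regions = []
    for i in range(rows):
        for j in range(cols):
            regions.append(
                Rect(
                    i * tolerance,
                    j * tolerance,
                    min((i + 1) * tolerance, h),
                    min((j + 1) * tolerance, w),
                )
            )
    grid = RegionGrid((h, w), tolerance, overlap, tuple(regions))
    for idx in range(grid.n_regions):
        exp = grid.expanded(idx)
        if exp.height < patch_size:
            raise InvalidGeometryError(
                f"expanded region {idx} height {exp.height} < patch size {patch_size}"
            )
        if exp.width < patch_size:
            raise InvalidGeometryError(
                f"expanded region {idx} width {exp.width} < patch size {patch_size}"
            )
    return grid


def _region_pixels(image: np.ndarray, rect: Rect) -> np.ndarray:
    """Flattened all-channel pixel vector of a region."""
    block = image[rect.r0 : rect.r1, rect.c0 : rect.c1]
    return np.asarray(block, dtype=np.float64).ravel()


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation; 0 for zero-variance input (constant regions
    carry no evidence for or against alignment)."""
    su, sv = u.std(), v.std()
    if su == 0.0 or sv == 0.0:
        return 0.0
    return float(np.mean((u - u.mean()) * (v - v.mean())) / (su * sv))


def compute_sampling_distribution(
    source: np.ndarray,
    target: np.ndarray,
    grid: RegionGrid,
    bins: int = 64,
    value_range: tuple[float, float] = (0.0, 1.0),
    histogram_source: str = "source",
) -> SamplingDistribution:
    """Evaluate the global sampling rule for one image pair.

    ``histogram_source`` selects which domain's pixels the region histograms
    H_i are computed from ("source", "target" or "joint").
    """
    if source.shape[:2] != grid.image_shape or target.shape[:2] != grid.image_shape:
        raise ContractError(
            f"images {source.shape[:2]}/{target.shape[:2]} do not match grid {grid.image_shape}"
        )
    if bins < 2:
        raise ContractError(f"bins must be >= 2, got {bins}")
    if histogram_source not in ("source", "target", "joint"):
        raise ContractError(f"unknown histogram_source {histogram_source!r}")

    # correlation uses flattened all-channel vectors when the domains share a
    # channel count, channel-collapsed intensity otherwise
    same_channels = (source.ndim == target.ndim) and (
        source.ndim == 2 or source.shape[-1] == target.shape[-1]
    )

    def _intensity(img: np.ndarray, rect: Rect) -> np.ndarray:
        block = np.asarray(img[rect.r0 : rect.r1, rect.c0 : rect.c1], dtype=np.float64)
        return block.mean(axis=-1).ravel() if block.ndim == 3 else block.ravel()

    n = grid.n_regions
    H = np.zeros((n, bins))
    corr = np.zeros(n)
    for i, rect in enumerate(grid.regions):
        s = _region_pixels(source, rect)
        t = _region_pixels(target, rect)
        if same_channels:
            corr[i] = _pearson(s, t)
        else:
            corr[i] = _pearson(_intensity(source, rect), _intensity(target, rect))
        if histogram_source == "source":
            pix = s
        elif histogram_source == "target":
            pix = t
        else:
            pix = np.concatenate([s, t])
        hist, _ = np.histogram(pix, bins=bins, range=value_range)
        H[i] = hist / hist.sum()

    denom = H @ H.sum(axis=0)  # denom[i] = sum_j H_i . H_j
    Q = (1.0 + corr) / denom
    total = Q.sum()
    if total <= 0.0:
        raise DegenerateDistributionError(
            "all region scores are zero; fall back to uniform region sampling"
        )
    P = Q / total
    return SamplingDistribution(H=H, Q=Q, P=P)


def sample_patch_pair(
    source: np.ndarray,
    target: np.ndarray,
    grid: RegionGrid,
    dist: SamplingDistribution,
    patch_size: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Draw one training patch pair.

    The region is drawn from Categorical(P); the source and target patches
    are cropped at *independent* uniform positions inside the expanded
    region, so pixelwise registration within a region is never assumed.
    """
    if len(dist.P) != grid.n_regions:
        raise ContractError("sampling distribution does not match grid")
    k = int(rng.choice(grid.n_regions, p=dist.P))
    exp = grid.expanded(k)
    if exp.height < patch_size or exp.width < patch_size:
        raise InvalidGeometryError(
            f"patch size {patch_size} exceeds expanded region {k} "
            f"({exp.height}x{exp.width})"
        )
    sr = exp.r0 + int(rng.integers(0, exp.height - patch_size + 1))
    sc = exp.c0 + int(rng.integers(0, exp.width - patch_size + 1))
    tr = exp.r0 + int(rng.integers(0, exp.height - patch_size + 1))
    tc = exp.c0 + int(rng.integers(0, exp.width - patch_size + 1))
    sp = source[sr : sr + patch_size, sc : sc + patch_size]
    tp = target[tr : tr + patch_size, tc : tc + patch_size]
    return sp, tp, k
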