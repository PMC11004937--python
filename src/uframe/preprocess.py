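"""Intensity normalisation, gradient channels and affine registration.

The preprocessing chain mirrors how raw widefield/autofluorescence
acquisitions are conditioned before training: background noise is
characterised with Otsu's threshold plus an interquartile-range outlier
fence, the brightest 0.1% of pixels are saturated, and intensities are
linearly rescaled to the unit interval.  Single-channel inputs can be
augmented with the two Sobel-Feldman derivatives as extra channels.
Registration is coarse-to-fine: a least-squares affine from landmark points,
then a local affine refinement maximising Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ContractError, RankDeficiencyError, UndefinedCorrelationError
from .tolerance import pearson_correlation_flagged

__all__ = [
    "IntensityReport",
    "intensity_scale",
    "sobel_derivatives",
    "sobel_channels",
    "affine_from_points",
    "refine_local_affine",
    "LocalSearchConfig",
]

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)


@dataclass(frozen=True)
class IntensityReport:
    """Diagnostics from intensity scaling.

    ``background_fence`` (Q3 + 1.5*IQR of the sub-threshold pixels) is a QC
    ceiling on plausible background values; it is recorded, not applied.
    """

    otsu_threshold: float | None
    background_fence: float | None
    clip_value: float | None
    degenerate: bool = False


def intensity_scale(image: np.ndarray) -> tuple[np.ndarray, IntensityReport]:
    """Normalise intensities to [0, 1] with 0.1% highlight saturation.

    Otsu's threshold separates background; the interquartile fence of the
    background pixels is recorded for QC.  Values above the 99.9th
    percentile are clipped, then the image is rescaled linearly.  A constant
    image is returned as zeros with a degenerate flag.
    """
    img = np.asarray(image, dtype=np.float64)
    lo = img.min()
    if img.max() == lo:
        return np.zeros_like(img), IntensityReport(None, None, None, degenerate=True)
    thr = float(threshold_otsu(img))
    background = img[img < thr]
    if background.size >= 4:
        q1, q3 = np.percentile(background, [25, 75])
        fence = float(q3 + 1.5 * (q3 - q1))
    else:
        fence = None
    # "higher" interpolation makes the transform idempotent: once the top
    # 0.1% sit at exactly 1.0, the next pass finds clip == 1.0 and is a no-op
    clip = float(np.quantile(img, 0.999, method="higher"))
    if clip <= lo:  # pathological histogram: fall back to the maximum
        clip = float(img.max())
    scaled = np.clip((img - lo) / (clip - lo), 0.0, 1.0)
    return scaled, IntensityReport(thr, fence, clip)


def sobel_derivatives(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw Sobel-Feldman derivatives (Gx, Gy), reflect boundary handling.

    Kernel weights sum to 8, so a unit-step ramp yields |G| = 8 at interior
    pixels.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ContractError(f"expected single-channel 2-D image, got shape {img.shape}")
    if min(img.shape) < 3:
        raise ContractError("image sides must be >= 3 for the 3x3 Sobel kernels")
    gx = ndimage.correlate(img, _SOBEL_X, mode="reflect")
    gy = ndimage.correlate(img, _SOBEL_X.T, mode="reflect")
    return gx, gy


def sobel_channels(image: np.ndarray) -> np.ndarray:
    """Stack [original, Gx, Gy] as a 3-channel image.

    Derivatives are scaled symmetrically about zero onto the 8-bit range —
    zero gradient maps to mid-range (128), the extremes +-8*(input range)
    saturate at 0/255 — and returned as uint8 channels.  The original
    channel is passed through unchanged (cast to uint8 for integer input).
    """
    img = np.asarray(image)
    gx, gy = sobel_derivatives(img)
    rng_in = float(img.max()) - float(img.min())
    scale = 8.0 * rng_in if rng_in > 0 else 1.0

    def to_u8(g):
        return np.clip(np.round(g / scale * 127.5 + 127.5), 0, 255).astype(np.uint8)

    if np.issubdtype(img.dtype, np.integer):
        base = np.clip(img, 0, 255).astype(np.uint8)
    else:
        span = rng_in if rng_in > 0 else 1.0
        base = np.clip(
            np.round((img.astype(np.float64) - img.min()) / span * 255), 0, 255
        ).astype(np.uint8)
    return np.stack([base, to_u8(gx), to_u8(gy)], axis=-1)


def affine_from_points(
    src_points: np.ndarray, dst_points: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Least-squares 2x3 affine mapping src (x, y) points onto dst points.

    Requires >= 3 non-collinear correspondences.  Returns the affine and a
    residual report (per-point residuals and their RMS).
    """
    src = np.asarray(src_points, dtype=np.float64)
    dst = np.asarray(dst_points, dtype=np.float64)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ContractError("point lists must be matching (n, 2) arrays")
    n = src.shape[0]
    if n < 3:
        raise RankDeficiencyError(f"need >= 3 point pairs, got {n}")
    A = np.hstack([src, np.ones((n, 1))])
    if np.linalg.matrix_rank(A) < 3:
        raise RankDeficiencyError("source points are collinear; affine is underdetermined")
    coeffs, *_ = np.linalg.lstsq(A, dst, rcond=None)
    affine = coeffs.T  # 2x3, rows = (a, b, tx), (c, d, ty)
    residuals = dst - A @ coeffs
    per_point = np.linalg.norm(residuals, axis=1)
    report = {"residuals": per_point, "rms": float(np.sqrt((per_point**2).mean()))}
    return affine, report


@dataclass(frozen=True)
class LocalSearchConfig:
    """Pattern-search ranges/steps for local affine refinement.

    Translations in pixels, rotation/shear in radians, scale multiplicative.
    Steps shrink by half ``n_shrink`` times; the search is deterministic.
    """

    max_translation: float = 8.0
    max_rotation: float = 0.1
    max_scale: float = 0.1
    max_shear: float = 0.05
    initial_step: float = 2.0
    n_shrink: int = 4
    max_iter: int = 40


def _affine_matrix(params: np.ndarray) -> np.ndarray:
    tx, ty, scale, rot, shear = params
    c, s = np.cos(rot), np.sin(rot)
    rot_m = np.array([[c, -s], [s, c]])
    shear_m = np.array([[1.0, shear], [0.0, 1.0]])
    lin = (1.0 + scale) * rot_m @ shear_m
    return np.hstack([lin, [[tx], [ty]]])


def _sample_window(target: np.ndarray, affine: np.ndarray, shape, origin) -> np.ndarray:
    """Bilinearly sample the target under the affine at patch pixel centres."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    xy = np.stack([cc.ravel() + origin[1], rr.ravel() + origin[0]])  # (x, y)
    mapped = affine[:, :2] @ xy + affine[:, 2:]
    coords = np.stack([mapped[1], mapped[0]])  # map_coordinates wants (row, col)
    return ndimage.map_coordinates(
        np.asarray(target, dtype=np.float64), coords, order=1, mode="nearest"
    ).reshape(h, w)


def refine_local_affine(
    src_patch: np.ndarray,
    target_image: np.ndarray,
    init_affine: np.ndarray,
    cfg: LocalSearchConfig | None = None,
    origin: tuple[int, int] = (0, 0),
) -> tuple[np.ndarray, float]:
    """Refine an affine by maximising Pearson correlation.

    Coordinate-wise pattern search over (tx, ty, scale, rotation, shear)
    offsets from ``init_affine`` with shrinking steps.  The returned
    correlation is never below that of the initial affine.  ``origin`` is
    the (row, col) of the patch's upper-left corner in the source frame.
    """
    cfg = cfg or LocalSearchConfig()
    patch = np.asarray(src_patch, dtype=np.float64)
    if patch.ndim != 2:
        raise ContractError("src_patch must be single-channel 2-D")
    if patch.std() == 0:
        raise UndefinedCorrelationError("constant source patch: correlation undefined")
    init_affine = np.asarray(init_affine, dtype=np.float64)
    if init_affine.shape != (2, 3):
        raise ContractError("init affine must be 2x3")

    def score(params) -> float:
        delta = _affine_matrix(params)
        # compose: apply init, then the local delta around the init position
        lin = delta[:, :2] @ init_affine[:, :2]
        trans = delta[:, :2] @ init_affine[:, 2:] + delta[:, 2:]
        window = _sample_window(target_image, np.hstack([lin, trans]), patch.shape, origin)
        r, degenerate = pearson_correlation_flagged(patch.ravel(), window.ravel())
        return -np.inf if degenerate else r

    bounds = np.array(
        [
            cfg.max_translation,
            cfg.max_translation,
            cfg.max_scale,
            cfg.max_rotation,
            cfg.max_shear,
        ]
    )
    steps = np.array(
        [cfg.initial_step, cfg.initial_step, cfg.max_scale / 2, cfg.max_rotation / 2, cfg.max_shear / 2]
    )
    params = np.zeros(5)
    best = score(params)
    for _ in range(cfg.n_shrink + 1):
        for _ in range(cfg.max_iter):
            improved = False
            for axis in range(5):
                for sign in (+1.0, -1.0):
                    cand = params.copy()
                    cand[axis] = np.clip(cand[axis] + sign * steps[axis], -bounds[axis], bounds[axis])
                    sc = score(cand)
                    if sc > best:
                        best, params, improved = sc, cand, True
            if not improved:
                break
        steps = steps / 2.0
    delta = _affine_matrix(params)
    lin = delta[:, :2] @ init_affine[:, :2]
    trans = delta[:, :2] @ init_affine[:, 2:] + delta[:, 2:]
    init_score = score(np.zeros(5))
    if init_score > best:  # defensive; pattern search starts at init
        return init_affine, float(init_score)
    return np.hstack([lin, trans]), float(best)
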