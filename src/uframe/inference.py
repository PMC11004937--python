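"""Full-image translation by overlapped tiling, and image-quality metrics.

Patch-trained generators are fully convolutional, so a large image is
translated tile by tile: tiles overlap by a halo at least as wide as the
generator's receptive-field radius and only each tile's central core is
written to the output, which keeps seams consistent for purely local
(normalisation-free) networks.

Quality is quantified by multiscale structural similarity (MS-SSIM) with the
canonical five scale weights and by peak signal-to-noise ratio
PSNR = 10*log10(range^2 / MSE).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .data import from_chw, to_chw
from .errors import ContractError
from .networks import NetworkBundle, WidthConfig
from .nn.autograd import Tensor, no_grad

__all__ = [
    "receptive_radius",
    "translate_tiled",
    "ms_ssim",
    "psnr",
    "image_metrics",
]


# ------------------------------------------------------------------ tiling
def receptive_radius(width: WidthConfig) -> int:
    """Receptive-field radius of the encoder-decoder generator in pixels.

    Each 3x3 convolution adds kernel_radius * (downsampling factor at which
    it acts); nearest-neighbour upsampling adds nothing.  For the standard
    stack: stem (+1), two downsamplings (+1, +2), 2*n_res bottleneck convs
    at factor 4 on each side (+16*n_res), decoder convs (+2, +1, +1).
    """
    return 8 + 16 * width.n_res


def _pad_to(img: np.ndarray, h: int, w: int) -> np.ndarray:
    ph, pw = h - img.shape[-2], w - img.shape[-1]
    if ph == 0 and pw == 0:
        return img
    return np.pad(img, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")


def _as_module(model, direction: str):
    if isinstance(model, NetworkBundle):
        if direction == "st":
            return model.generator_st()
        if direction == "ts":
            return model.generator_ts()
        raise ContractError(f"direction must be 'st' or 'ts', got {direction!r}")
    return model


def _run(module, window: np.ndarray) -> np.ndarray:
    h, w = window.shape[-2:]
    h4, w4 = -(-h // 4) * 4, -(-w // 4) * 4
    padded = _pad_to(window, h4, w4)
    with no_grad():
        out = module(Tensor(padded)).data
    return out[..., :h, :w]


def translate_tiled(
    image: np.ndarray,
    model,
    direction: str = "st",
    tile: int = 256,
    halo: int | None = None,
) -> np.ndarray:
    """Translate a full-size image with a patch-trained generator.

    ``model`` is a NetworkBundle (with ``direction`` "st" or "ts") or any
    module mapping (1, C, h, w) to (1, C', h, w).  Images smaller than one
    tile fall back to a single whole-image pass.  Output spatial size always
    equals the input's.
    """
    module = _as_module(model, direction)
    if halo is None:
        halo = receptive_radius(getattr(model, "width", WidthConfig()))
    if tile < 2 * halo + 1:
        raise ContractError(f"tile {tile} must be >= 2*halo + 1 = {2 * halo + 1}")
    x = to_chw(image)
    _, c, h, w = x.shape
    if h <= tile and w <= tile:
        return from_chw(_run(module, x))

    core = tile - 2 * halo
    xp = np.pad(x, ((0, 0), (0, 0), (halo, 0), (halo, 0)), mode="reflect")
    need_h = halo + h + tile  # generous right/bottom margin
    need_w = halo + w + tile
    xp = np.pad(
        xp,
        ((0, 0), (0, 0), (0, need_h - xp.shape[2]), (0, need_w - xp.shape[3])),
        mode="reflect",
    )
    out = None
    for r0 in range(0, h, core):
        rows = min(core, h - r0)
        for c0 in range(0, w, core):
            cols = min(core, w - c0)
            window = xp[:, :, r0 : r0 + tile, c0 : c0 + tile]
            y = _run(module, window)
            if out is None:
                out = np.zeros((1, y.shape[1], h, w), dtype=y.dtype)
            out[:, :, r0 : r0 + rows, c0 : c0 + cols] = y[
                :, :, halo : halo + rows, halo : halo + cols
            ]
    return from_chw(out)


# ----------------------------------------------------------------- metrics
_MSSSIM_WEIGHTS = np.array([0.0448, 0.2856, 0.3001, 0.2363, 0.1333])
_K1, _K2 = 0.01, 0.03
_WIN_SIGMA = 1.5
_WIN_TRUNCATE = (11 - 1) / 2 / _WIN_SIGMA  # 11-tap gaussian window


def _gauss(img: np.ndarray) -> np.ndarray:
    return ndimage.gaussian_filter(img, _WIN_SIGMA, truncate=_WIN_TRUNCATE, mode="reflect")

def _ssim_components(x: np.ndarray, y: np.ndarray, data_range: float):
    """Mean luminance term and mean contrast-structure term of SSIM."""
    c1 = (_K1 * data_range) ** 2
    c2 = (_K2 * data_range) ** 2
    mx, my = _gauss(x), _gauss(y)
    sxx = _gauss(x * x) - mx * mx
    syy = _gauss(y * y) - my * my
    sxy = _gauss(x * y) - mx * my
    lum = (2 * mx * my + c1) / (mx**2 + my**2 + c1)
    cs = (2 * sxy + c2) / (sxx + syy + c2)
    return float((lum * cs).mean()), float(cs.mean())


def _downsample2(img: np.ndarray) -> np.ndarray:
    h, w = img.shape
    h2, w2 = h - h % 2, w - w % 2
    return img[:h2, :w2].reshape(h2 // 2, 2, w2 // 2, 2).mean(axis=(1, 3))


def _ms_ssim_single(x: np.ndarray, y: np.ndarray, data_range: float) -> float:
    max_scales = len(_MSSSIM_WEIGHTS)
    # each extra scale halves resolution; the 11-tap window must still fit
    feasible = 1
    side = min(x.shape)
    while feasible < max_scales and (side // 2 ** feasible) >= 11:
        feasible += 1
    if feasible < max_scales:
        warnings.warn(
            f"image sides {x.shape} support only {feasible} MS-SSIM scales; "
            "weights renormalised",
            stacklevel=3,
        )
    weights = _MSSSIM_WEIGHTS[:feasible] / _MSSSIM_WEIGHTS[:feasible].sum()
    vals = []
    for scale in range(feasible):
        ssim_mean, cs_mean = _ssim_components(x, y, data_range)
        vals.append(ssim_mean if scale == feasible - 1 else cs_mean)
        if scale != feasible - 1:
            x, y = _downsample2(x), _downsample2(y)
    vals = np.maximum(np.asarray(vals), 0.0)  # clamp negative structure terms
    return float(np.prod(vals**weights))


def _infer_range(x: np.ndarray, y: np.ndarray) -> float:
    if np.issubdtype(x.dtype, np.integer) or np.issubdtype(y.dtype, np.integer):
        return 255.0
    return 1.0


def ms_ssim(x: np.ndarray, y: np.ndarray, data_range: float | None = None) -> float:
    """Multiscale SSIM in [0, 1]; channels are averaged."""
    if x.shape != y.shape:
        raise ContractError(f"shape mismatch: {x.shape} vs {y.shape}")
    if data_range is None:
        data_range = _infer_range(x, y)
    xf = np.asarray(x, dtype=np.float64)
    yf = np.asarray(y, dtype=np.float64)
    if xf.ndim == 2:
        return _ms_ssim_single(xf, yf, data_range)
    return float(
        np.mean([_ms_ssim_single(xf[..., c], yf[..., c], data_range) for c in range(xf.shape[-1])])
    )


def psnr(x: np.ndarray, y: np.ndarray, data_range: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    if x.shape != y.shape:
        raise ContractError(f"shape mismatch: {x.shape} vs {y.shape}")
    if data_range is None:
        data_range = _infer_range(x, y)
    mse = float(np.mean((np.asarray(x, np.float64) - np.asarray(y, np.float64)) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / mse))


def image_metrics(
    x: np.ndarray, y: np.ndarray, data_range: float | None = None
) -> tuple[float, float]:
    """Return (MS-SSIM, PSNR) for an image pair of equal shape."""
    return ms_ssim(x, y, data_range), psnr(x, y, data_range)
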