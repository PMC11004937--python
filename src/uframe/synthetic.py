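"""Synthetic roughly paired microscopy-like datasets with known ground truth.

The generator emulates the structure the framework is built for: an image is
a grid of texture cells (the true "region" scale), each cell carrying its
own procedural texture — elliptical blob fields standing in for nuclei, or
oriented fibre bands standing in for stroma.  Cells share a common mean
intensity, so their identity lives in texture (orientation, granularity)
rather than brightness: local crops carry a strong cell signature while
large crops average it away, which is what makes the cell scale
recoverable by the tolerance search.

The delivered target is the appearance-mapped source degraded the way real
roughly paired data are: a small global affine jitter (slide placement), a
per-patch displacement of fixed Euclidean norm ``misalign_d`` (emulating
patch pairing at a fixed distance), and additive Gaussian noise.
The aligned ground-truth target is returned alongside for evaluation only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ContractError, InvalidGeometryError

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "APPEARANCE_MAPS",
    "regionwise_paired_spec",
    "generate_dataset",
    "apply_misalignment",
    "scramble_subcells",
    "write_dataset",
]


# ------------------------------------------------------- appearance mappings
def _invert_gamma_fwd(s: np.ndarray) -> np.ndarray:
    return (1.0 - s) ** 1.3


def _invert_gamma_inv(t: np.ndarray) -> np.ndarray:
    return 1.0 - np.clip(t, 0.0, 1.0) ** (1.0 / 1.3)


def _hema_fwd(s: np.ndarray) -> np.ndarray:
    """Monotone 1->3 channel map loosely emulating an H&E look-up."""
    r = 1.0 - 0.75 * s**1.2
    g = 1.0 - 0.90 * s
    b = 1.0 - 0.45 * s**0.8
    return np.stack([r, g, b], axis=-1)


def _hema_inv(t: np.ndarray) -> np.ndarray:
    return np.clip((1.0 - t[..., 1]) / 0.90, 0.0, 1.0)


def _gamma_contrast_fwd(s: np.ndarray) -> np.ndarray:
    return 0.1 + 0.85 * s**2.0


def _gamma_contrast_inv(t: np.ndarray) -> np.ndarray:
    return np.sqrt(np.clip((t - 0.1) / 0.85, 0.0, 1.0))


APPEARANCE_MAPS: dict[str, tuple] = {
    "identity": (lambda s: s.copy(), lambda t: t.copy()),
    "invert-gamma": (_invert_gamma_fwd, _invert_gamma_inv),
    "gamma-contrast": (_gamma_contrast_fwd, _gamma_contrast_inv),
    "hema-mix": (_hema_fwd, _hema_inv),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the fixture generator.

    ``cell_size`` is the texture grid pitch (the scale at which the region
    assumption holds); ``misalign_d`` the Euclidean norm, in pixels, of every
    per-patch displacement applied to the delivered target; the ``jitter_*``
    ranges bound the global affine perturbation; ``noise_sigma`` the additive
    Gaussian noise on the delivered target.
    """

    image_size: int = 1024
    cell_size: int = 256
    appearance: str = "invert-gamma"
    misalign_mode: str = "displace"  # "displace" (fixed-norm) or "scramble" (within-cell)
    misalign_d: float = 256.0
    jitter_shift: float = 8.0
    jitter_rotation: float = 0.02
    jitter_scale: float = 0.02
    noise_sigma: float = 0.01
    illumination_strength: float = 0.0
    illumination_scale: float | None = None  # correlation length; None -> 2*cell_size
    texture_gain: float = 1.0  # multiplies the per-cell contrast target
    seed: int = 0

    def __post_init__(self):
        if self.misalign_d < 0:
            raise ContractError("misalign_d must be >= 0")
        if self.misalign_mode not in ("displace", "scramble"):
            raise ContractError(f"unknown misalign_mode {self.misalign_mode!r}")
        if self.appearance not in APPEARANCE_MAPS:
            raise ContractError(
                f"unknown appearance map {self.appearance!r}; "
                f"available: {sorted(APPEARANCE_MAPS)}"
            )
        if self.misalign_d > self.image_size / 2:
            raise InvalidGeometryError(
                f"misalign_d {self.misalign_d} exceeds half the image side"
            )


def regionwise_paired_spec(
    cell_size: int = 64, image_size: int = 512, seed: int = 0
) -> SyntheticSpec:
    """Benchmark configuration for regionwise-paired data.

    Cell-level statistics match between the domains while sub-cell positions
    are scrambled (within-cell permutation of half-cell blocks), with a
    smooth target-only illumination field and moderate noise — the regime
    where region-level learning is the right model and the cell size is the
    recoverable tolerance scale.
    """
    return SyntheticSpec(
        image_size=image_size,
        cell_size=cell_size,
        appearance="invert-gamma",
        misalign_mode="scramble",
        misalign_d=0.0,
        jitter_shift=0.0,
        jitter_rotation=0.0,
        jitter_scale=0.0,
        noise_sigma=0.05,
        illumination_strength=0.35,
        seed=seed,
    )


@dataclass
class SyntheticDataset:
    source: np.ndarray
    target_true: np.ndarray  # appearance-mapped source, pixel-aligned
    target: np.ndarray  # delivered: jittered, displaced, noisy
    manifest: dict = field(repr=False)


# ----------------------------------------------------------------- textures
def _fiber_cell(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Oriented bright ridges on a dark background.

    The rectified carrier gives the strong positive skew of fluorescence-like
    signal (sparse bright structure, dark background); a symmetric sinusoid
    would make an image and its contrast flip nearly indistinguishable in
    distribution, which no real acquisition is.
    """
    theta = rng.uniform(0, np.pi)
    wavelength = rng.uniform(h / 14, h / 7)
    phase = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    carrier = np.sin(
        2 * np.pi * (np.cos(theta) * xx + np.sin(theta) * yy) / wavelength + phase
    )
    tex = 0.12 + 0.75 * np.maximum(carrier, 0.0) ** 1.5
    tex += rng.normal(0, 0.04, tex.shape)
    return tex


def _blob_cell(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    radius = rng.uniform(h / 18, h / 10)
    ecc = rng.uniform(1.6, 3.0)
    orient = rng.uniform(0, np.pi)
    count = max(4, int(0.18 * h * w / (np.pi * radius**2)))
    tex = np.full((h, w), 0.12)
    c, s = np.cos(orient), np.sin(orient)
    for _ in range(count):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        half = int(np.ceil(3 * radius * ecc))
        y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
        x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        u = (xx - cx) * c + (yy - cy) * s
        v = -(xx - cx) * s + (yy - cy) * c
        bump = np.exp(-0.5 * ((u / (radius * ecc)) ** 2 + (v / radius) ** 2))
        tex[y0:y1, x0:x1] += 0.65 * bump
    tex += rng.normal(0, 0.03, tex.shape)
    return tex


_CELL_MEAN = 0.45
_CELL_GRAD_ENERGY = 0.035  # target mean |gradient| per cell


def _normalise_cell(tex: np.ndarray, gain: float = 1.0) -> np.ndarray:
    """Equalise each cell's mean intensity and mean gradient magnitude.

    Cell identity then lives in texture *pattern* (orientation, granularity)
    rather than in brightness or edge density, so coarse statistics carry no
    between-cell layout: what distinguishes cells is only visible at scales
    that resolve their structure.  Two passes, because clipping after the
    first rescale would otherwise re-introduce energy differences.
    """
    out = tex - tex.mean()
    for _ in range(2):
        gy, gx = np.gradient(out)
        energy = np.hypot(gx, gy).mean()
        if energy == 0:
            return np.full_like(tex, _CELL_MEAN)
        out = np.clip(
            _CELL_MEAN + (out - out.mean()) * (gain * _CELL_GRAD_ENERGY / energy),
            0.02,
            0.98,
        )
        out = out - out.mean() + _CELL_MEAN
    return np.clip(out, 0.0, 1.0)


def _render_source(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Tile the image with per-cell textures, blended across borders.

    Each cell is rendered on a margin-extended tile and accumulated under a
    raised-cosine weight, so cell boundaries carry no gradient seam (a seam
    lattice would be a strong artificial landmark shared by both domains at
    every scale).

    Fluctuations are accumulated as sum(w_i * (tex_i - mean)) and divided by
    sqrt(sum(w_i^2)): averaging independent textures would otherwise leave a
    gradient-energy dip along every border (a cell-period lattice visible at
    coarse scales in both domains).
    """
    n = spec.image_size
    c = spec.cell_size
    margin = max(4, c // 4)
    acc = np.zeros((n, n))
    wsq = np.zeros((n, n))
    for r0 in range(0, n, c):
        for c0 in range(0, n, c):
            h = min(c, n - r0) + 2 * margin
            w = min(c, n - c0) + 2 * margin
            cell = _fiber_cell(h, w, rng) if rng.random() < 0.5 else _blob_cell(h, w, rng)
            cell = _normalise_cell(cell, spec.texture_gain) - _CELL_MEAN
            wy = np.hanning(h + 2)[1:-1]
            wx = np.hanning(w + 2)[1:-1]
            weight = np.outer(wy, wx)
            y0, x0 = r0 - margin, c0 - margin
            sy0, sx0 = max(0, -y0), max(0, -x0)
            y1 = min(n, y0 + h)
            x1 = min(n, x0 + w)
            view = (slice(max(0, y0), y1), slice(max(0, x0), x1))
            cut = (
                slice(sy0, sy0 + y1 - max(0, y0)),
                slice(sx0, sx0 + x1 - max(0, x0)),
            )
            acc[view] += cell[cut] * weight[cut]
            wsq[view] += weight[cut] ** 2
    img = np.clip(_CELL_MEAN + acc / np.sqrt(np.maximum(wsq, 1e-12)), 0.0, 1.0)
    img = _equalise_cell_energy(img, c, spec.texture_gain)
    return _equalise_cell_energy(img, c, spec.texture_gain)


def _equalise_cell_energy(img: np.ndarray, cell: int, gain: float = 1.0) -> np.ndarray:
    """Flatten the residual per-cell gradient-energy layout.

    Blending and range clipping leave a few-percent energy contrast between
    cells; a smooth per-cell gain field (bilinearly interpolated, so no new
    seams) scales fluctuations so every cell's mean gradient magnitude sits
    at the common target.
    """
    n = img.shape[0]
    k = -(-n // cell)
    fluct = img - _CELL_MEAN
    gy = ndimage.sobel(fluct, axis=0, mode="reflect") / 8.0
    gx = ndimage.sobel(fluct, axis=1, mode="reflect") / 8.0
    mag = np.hypot(gx, gy)
    gains = np.ones((k, k))
    for i in range(k):
        for j in range(k):
            e = mag[i * cell : (i + 1) * cell, j * cell : (j + 1) * cell].mean()
            if e > 0:
                gains[i, j] = np.clip(gain * _CELL_GRAD_ENERGY / e, 0.5, 2.0)
    gain_map = np.kron(gains, np.ones((cell, cell)))[:n, :n]
    gain_map = ndimage.gaussian_filter(gain_map, cell / 3.0, mode="nearest")
    return np.clip(_CELL_MEAN + fluct * gain_map, 0.0, 1.0)


# ------------------------------------------------------------- degradations
def _global_affine_jitter(img: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator):
    """Small random similarity transform about the image centre."""
    if spec.jitter_shift == 0 and spec.jitter_rotation == 0 and spec.jitter_scale == 0:
        return img.copy(), {"rotation": 0.0, "scale": 1.0, "shift": [0.0, 0.0]}
    rot = rng.uniform(-spec.jitter_rotation, spec.jitter_rotation)
    scale = 1.0 + rng.uniform(-spec.jitter_scale, spec.jitter_scale)
    shift = rng.uniform(-spec.jitter_shift, spec.jitter_shift, size=2)
    h, w = img.shape[:2]
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    cs, sn = np.cos(rot), np.sin(rot)
    lin = scale * np.array([[cs, -sn], [sn, cs]])
    inv = np.linalg.inv(lin)
    offset = centre - inv @ (centre - shift)

    def warp(channel):
        return ndimage.affine_transform(channel, inv, offset=offset, order=1, mode="reflect")

    if img.ndim == 2:
        out = warp(img)
    else:
        out = np.stack([warp(img[..., k]) for k in range(img.shape[-1])], axis=-1)
    return out, {"rotation": float(rot), "scale": float(scale), "shift": shift.tolist()}


def _displacement_vector(d: float, rng: np.random.Generator, tries: int = 200):
    """Integer (dy, dx) with Euclidean norm within 0.5 of d."""
    if d == 0:
        return 0, 0
    for _ in range(tries):
        theta = rng.uniform(0, 2 * np.pi)
        dy = int(round(d * np.sin(theta)))
        dx = int(round(d * np.cos(theta)))
        if abs(np.hypot(dy, dx) - d) <= 0.5 and (dy, dx) != (0, 0):
            return dy, dx
    raise InvalidGeometryError(f"no integer displacement of norm ~{d} found")


def apply_misalignment(
    image: np.ndarray,
    d: float,
    patch_size: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Displace each grid patch by a vector of Euclidean norm ~d.

    Patches are visited in row-major order.  When the displaced window is
    disjoint from the patch, the two windows are swapped (a pixel
    permutation); when they overlap (d smaller than the patch diagonal) the
    patch is filled from the displaced window of the pristine input.
    Returns the displaced image and the per-patch displacement vectors.
    """
    img = np.asarray(image)
    h, w = img.shape[:2]
    if d > min(h, w) / 2:
        raise InvalidGeometryError(f"displacement {d} exceeds half the image side")
    out = img.copy()
    pristine = img.copy()
    vectors: list[tuple[int, int]] = []
    for r0 in range(0, h - patch_size + 1, patch_size):
        for c0 in range(0, w - patch_size + 1, patch_size):
            if d == 0:
                vectors.append((0, 0))
                continue
            for attempt in range(200):
                dy, dx = _displacement_vector(d, rng)
                r1, c1 = r0 + dy, c0 + dx
                if 0 <= r1 <= h - patch_size and 0 <= c1 <= w - patch_size:
                    break
            else:
                raise InvalidGeometryError(
                    f"no in-bounds displacement of norm {d} for patch at ({r0}, {c0})"
                )
            vectors.append((dy, dx))
            disjoint = abs(dy) >= patch_size or abs(dx) >= patch_size
            a = (slice(r0, r0 + patch_size), slice(c0, c0 + patch_size))
            b = (slice(r1, r1 + patch_size), slice(c1, c1 + patch_size))
            if disjoint:
                tmp = out[a].copy()
                out[a] = out[b]
                out[b] = tmp
            else:
                out[a] = pristine[b]
    return out, vectors


def scramble_subcells(
    image: np.ndarray,
    cell_size: int,
    block_size: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Permute sub-blocks within every cell (cell statistics preserved).

    Each ``cell_size`` cell is split into ``block_size`` tiles (default half
    the cell) which are randomly permuted inside the cell.  Pixelwise
    alignment below the cell scale is destroyed while every cell-level
    statistic is exactly preserved.  Returns the scrambled image and the
    per-block displacement vectors in row-major block order.
    """
    rng = rng or np.random.default_rng(0)
    block = block_size or cell_size // 2
    if block < 1 or cell_size % block != 0:
        raise ContractError(f"block size {block} must divide cell size {cell_size}")
    img = np.asarray(image)
    out = img.copy()
    h, w = img.shape[:2]
    k = cell_size // block
    vectors: list[tuple[int, int]] = []
    for r0 in range(0, h - cell_size + 1, cell_size):
        for c0 in range(0, w - cell_size + 1, cell_size):
            offsets = [(i * block, j * block) for i in range(k) for j in range(k)]
            perm = rng.permutation(len(offsets))
            cell = img[r0 : r0 + cell_size, c0 : c0 + cell_size].copy()
            for dst, src in enumerate(perm):
                (ri, ci), (rj, cj) = offsets[dst], offsets[int(src)]
                out[r0 + ri : r0 + ri + block, c0 + ci : c0 + ci + block] = cell[
                    rj : rj + block, cj : cj + block
                ]
                vectors.append((rj - ri, cj - ci))
    return out, vectors


def _illumination_field(
    shape, scale: float, strength: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth multiplicative gain field (unit mean) with correlation length
    ``scale`` — emulates vignetting / staining inhomogeneity of the target
    modality."""
    g = rng.normal(0.0, 1.0, shape[:2])
    g = ndimage.gaussian_filter(g, scale, mode="reflect")
    std = g.std()
    if std > 0:
        g = g / std
    return 1.0 + strength * g


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate one roughly paired source/target pair with ground truth.

    Deterministic for a fixed spec (byte-identical images for equal seeds).
    """
    rng = np.random.default_rng(spec.seed)
    source = _render_source(spec, rng)
    fwd, _ = APPEARANCE_MAPS[spec.appearance]
    target_true = np.clip(fwd(source), 0.0, 1.0)

    delivered, affine_params = _global_affine_jitter(target_true, spec, rng)
    if spec.misalign_mode == "scramble":
        delivered, vectors = scramble_subcells(delivered, spec.cell_size, rng=rng)
    else:
        delivered, vectors = apply_misalignment(
            delivered, spec.misalign_d, spec.cell_size, rng
        )
    if spec.illumination_strength > 0:
        scale = spec.illumination_scale or 2.0 * spec.cell_size
        field = _illumination_field(
            delivered.shape, scale, spec.illumination_strength, rng
        )
        if delivered.ndim == 3:
            field = field[..., None]
        delivered = np.clip(delivered * field, 0.0, 1.0)
    if spec.noise_sigma > 0:
        delivered = np.clip(
            delivered + rng.normal(0, spec.noise_sigma, delivered.shape), 0.0, 1.0
        )
    manifest = {
        "spec": asdict(spec),
        "global_affine": affine_params,
        "misalign_mode": spec.misalign_mode,
        "displacements": [list(v) for v in vectors],
    }
    return SyntheticDataset(
        source=source,
        target_true=target_true,
        target=delivered,
        manifest=manifest,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> Path:
    """Write source/target/target_true TIFFs plus the JSON manifest."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, img in (
        ("source", dataset.source),
        ("target", dataset.target),
        ("target_true", dataset.target_true),
    ):
        tifffile.imwrite(outdir / f"{name}.tif", img.astype(np.float32))
    (outdir / "manifest.json").write_text(json.dumps(dataset.manifest, indent=2))
    return outdir
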