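"""Reading and writing images, point lists and affine files."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import ContractError

__all__ = [
    "read_image",
    "write_image",
    "read_pair_folders",
    "read_points_csv",
    "write_affine",
    "read_affine",
]

_TIFF = {".tif", ".tiff"}


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF or PNG image as float64 in [0, 1] (integer types scaled)."""
    path = Path(path)
    if path.suffix.lower() in _TIFF:
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    img = np.asarray(img)
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(np.float64) / np.iinfo(img.dtype).max
    return img.astype(np.float64)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write float images as float32 TIFF or 8-bit PNG depending on suffix."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in _TIFF:
        tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    else:
        u8 = np.clip(np.round(np.asarray(image, dtype=np.float64) * 255), 0, 255).astype(
            np.uint8
        )
        iio.imwrite(path, u8)


def read_pair_folders(source_dir: str | Path, target_dir: str | Path):
    """Read matching-named images from two folders, sorted by filename."""
    source_dir, target_dir = Path(source_dir), Path(target_dir)
    exts = _TIFF | {".png"}
    s_files = sorted(p for p in source_dir.iterdir() if p.suffix.lower() in exts)
    t_files = sorted(p for p in target_dir.iterdir() if p.suffix.lower() in exts)
    if not s_files:
        raise ContractError(f"no images found in {source_dir}")
    if [p.stem for p in s_files] != [p.stem for p in t_files]:
        raise ContractError("source and target folders must contain matching filenames")
    return [(read_image(s), read_image(t), s.stem) for s, t in zip(s_files, t_files)]


def read_points_csv(path: str | Path) -> np.ndarray:
    """Two-column (x, y) CSV -> (n, 2) array; a header line is tolerated."""
    pts = np.genfromtxt(Path(path), delimiter=",", skip_header=0, dtype=np.float64)
    if pts.ndim == 1:
        pts = pts[None]
    if np.isnan(pts[0]).any():  # header row
        pts = pts[1:]
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ContractError(f"expected a 2-column point CSV at {path}")
    return pts


def write_affine(path: str | Path, affine: np.ndarray) -> None:
    np.savetxt(Path(path), np.asarray(affine, dtype=np.float64), fmt="%.12g")


def read_affine(path: str | Path) -> np.ndarray:
    a = np.loadtxt(Path(path))
    if a.shape != (2, 3):
        raise ContractError(f"affine file {path} must hold a 2x3 matrix")
    return a
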