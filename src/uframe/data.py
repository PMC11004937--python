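"""In-memory containers for roughly paired image data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError

__all__ = ["ImagePair", "to_chw", "from_chw"]


def _channels(image: np.ndarray) -> int:
    return 1 if image.ndim == 2 else image.shape[-1]


def to_chw(image: np.ndarray) -> np.ndarray:
    """HxW or HxWxC float array -> 1xCxHxW float32 batch element."""
    a = np.asarray(image, dtype=np.float32)
    if a.ndim == 2:
        a = a[None, None]
    elif a.ndim == 3:
        a = a.transpose(2, 0, 1)[None]
    else:
        raise ContractError(f"expected 2-D or 3-D image, got ndim={a.ndim}")
    return a


def from_chw(batch: np.ndarray) -> np.ndarray:
    """1xCxHxW -> HxW (C==1) or HxWxC."""
    a = np.asarray(batch)
    if a.ndim != 4 or a.shape[0] != 1:
        raise ContractError(f"expected a single-element batch, got shape {a.shape}")
    a = a[0]
    return a[0] if a.shape[0] == 1 else a.transpose(1, 2, 0)


@dataclass
class ImagePair:
    """A source image and a target image sharing a coordinate frame.

    Images are HxW (grayscale) or HxWxC arrays; ``value_range`` declares the
    intensity range the data were scaled to (default the unit interval, the
    output of the preprocessing pipeline).
    """

    source: np.ndarray
    target: np.ndarray
    value_range: tuple[float, float] = (0.0, 1.0)
    name: str = ""
    source_channels: int = field(init=False)
    target_channels: int = field(init=False)

    def __post_init__(self):
        if self.source.shape[:2] != self.target.shape[:2]:
            raise ContractError(
                f"source {self.source.shape[:2]} and target {self.target.shape[:2]} "
                "must share spatial shape"
            )
        self.source_channels = _channels(self.source)
        self.target_channels = _channels(self.target)

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.source.shape[:2]
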