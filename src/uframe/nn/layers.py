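"""Neural-network modules built on the autograd engine.

Mirrors the familiar Module/Parameter idiom: modules own named parameters,
compose hierarchically, and expose flat ``state_dict`` round-tripping for
checkpoints.  Weight *initialisation policy* (Kaiming for generators, narrow
normal for discriminators) lives in :mod:`uframe.training`; layers here start
from a generic Kaiming draw so they are usable standalone.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "Linear",
    "InstanceNorm2d",
    "LeakyReLU",
    "ReLU",
    "Sigmoid",
    "Upsample2x",
    "GlobalAvgPool",
    "Softmax",
    "ResidualBlock",
]

_DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=_DTYPE), requires_grad=True)


class Module:
    """Base class: child modules and parameters are discovered by attribute."""

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch; missing={sorted(missing)}, extra={sorted(extra)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=_DTYPE).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 stride: int = 1, padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = kernel_size // 2 if padding is None else padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, kernel_size, kernel_size))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    @property
    def fan_in(self) -> int:
        return self.in_channels * self.kernel_size**2

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / in_features), (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    @property
    def fan_in(self) -> int:
        return self.in_features

    def forward(self, x: Tensor) -> Tensor:
        return ag.linear(x, self.weight, self.bias)


class InstanceNorm2d(Module):
    """Per-sample, per-channel spatial normalisation (no affine parameters)."""

    def __init__(self, eps: float = 1e-5):
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ag.instance_norm(x, self.eps)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return ag.leaky_relu(x, self.slope)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.sigmoid(x)


class Upsample2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.upsample_nearest2x(x)


class GlobalAvgPool(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.global_avg_pool(x)


class GlobalMeanStdPool(Module):
    """Concatenate per-channel spatial mean and spatial std: (B,C,H,W) -> (B,2C)."""

    def forward(self, x: Tensor) -> Tensor:
        m = ag.global_avg_pool(x)
        m2 = ag.global_avg_pool(ag.mul(x, x))
        var = ag.add(m2, ag.mul(ag.mul(m, m), -1.0))
        return ag.concat([m, ag.sqrt(var, eps=1e-8)], axis=-1)


class Softmax(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.softmax(x, axis=-1)


class ResidualBlock(Module):
    """Two 3x3 convolutions with instance norm and a skip connection."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        self.conv1 = Conv2d(channels, channels, 3, rng=rng)
        self.norm1 = InstanceNorm2d()
        self.act = ReLU()
        self.conv2 = Conv2d(channels, channels, 3, rng=rng)
        self.norm2 = InstanceNorm2d()

    def forward(self, x: Tensor) -> Tensor:
        h = self.act(self.norm1(self.conv1(x)))
        h = self.norm2(self.conv2(h))
        return ag.add(x, h)
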