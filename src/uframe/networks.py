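"""Dual-generator / dual-discriminator architecture with a shared latent space.

Each generator is an encoder-decoder: the encoders of both domains project
into latent tensors of identical shape, so a source image can be decoded by
the target decoder (translation) or its own decoder (reconstruction).  The
discriminators are (N+1)-way classifiers over image patches: N nodes for the
real spatial regions of the training grid plus a single node shared by all
fake (generated) patches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ContractError, MemoryFloorError
from .nn import autograd as ag
from .nn.autograd import Tensor

__all__ = ["WidthConfig", "Generator", "Discriminator", "NetworkBundle", "build_networks"]


@dataclass(frozen=True)
class WidthConfig:
    """Capacity knobs for the convolutional stacks.

    ``base_filters`` is the stem width (doubled at each of the two stride-2
    downsamplings), ``n_res`` the number of residual blocks at the bottleneck,
    ``head_cap`` the largest admissible discriminator head width N+1 (the
    memory floor tied to the tolerance lower bound).
    """

    base_filters: int = 32
    n_res: int = 4
    head_cap: int = 4096
    norm: bool = True

    @classmethod
    def tiny(cls) -> "WidthConfig":
        """Preset small enough for CPU test runs."""
        return cls(base_filters=8, n_res=1)


def _maybe_norm(width: WidthConfig) -> list[nn.Module]:
    return [nn.InstanceNorm2d()] if width.norm else []


class Encoder(nn.Module):
    """Conv stem + two stride-2 downsamplings + residual bottleneck."""

    def __init__(self, in_channels: int, width: WidthConfig, rng: np.random.Generator):
        f = width.base_filters
        layers: list[nn.Module] = [nn.Conv2d(in_channels, f, 3, rng=rng)]
        layers += _maybe_norm(width) + [nn.ReLU()]
        layers += [nn.Conv2d(f, 2 * f, 3, stride=2, rng=rng)]
        layers += _maybe_norm(width) + [nn.ReLU()]
        layers += [nn.Conv2d(2 * f, 4 * f, 3, stride=2, rng=rng)]
        layers += _maybe_norm(width) + [nn.ReLU()]
        layers += [nn.ResidualBlock(4 * f, rng=rng) for _ in range(width.n_res)]
        self.net = nn.Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


class Decoder(nn.Module):
    """Residual bottleneck + two nearest-neighbour upsamplings, sigmoid output."""

    def __init__(self, out_channels: int, width: WidthConfig, rng: np.random.Generator):
        f = width.base_filters
        layers: list[nn.Module] = [nn.ResidualBlock(4 * f, rng=rng) for _ in range(width.n_res)]
        layers += [nn.Upsample2x(), nn.Conv2d(4 * f, 2 * f, 3, rng=rng)]
        layers += _maybe_norm(width) + [nn.ReLU()]
        layers += [nn.Upsample2x(), nn.Conv2d(2 * f, f, 3, rng=rng)]
        layers += _maybe_norm(width) + [nn.ReLU()]
        layers += [nn.Conv2d(f, out_channels, 3, rng=rng), nn.Sigmoid()]
        self.net = nn.Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


class Generator(nn.Module):
    pass  # marker base so initialisation policy can tell G from D


class Discriminator(nn.Module):
    """Patch-level classifier: stride-2 conv stack + (N+1)-channel conv head.

    The head is convolutional — every spatial position of the final feature
    map gets its own (N+1)-way softmax — and the cross-entropy averages over
    positions.  Instance norm sits between the conv layers (never before a
    global pool, where it would cancel the pooled statistics): it rescales
    activations so the narrow Normal(0, 0.02) weight initialisation still
    produces informative features, and the dense per-position logits give
    the generators a far richer gradient than a single global decision.
    """

    def __init__(self, in_channels: int, n_classes: int, width: WidthConfig,
                 rng: np.random.Generator):
        f = width.base_filters
        layers: list[nn.Module] = [nn.Conv2d(in_channels, f, 3, stride=2, rng=rng), nn.LeakyReLU(0.2)]
        layers += [nn.Conv2d(f, 2 * f, 3, stride=2, rng=rng), nn.InstanceNorm2d(), nn.LeakyReLU(0.2)]
        layers += [nn.Conv2d(2 * f, 4 * f, 3, stride=2, rng=rng), nn.InstanceNorm2d(), nn.LeakyReLU(0.2)]
        self.features = nn.Sequential(*layers)
        self.head = nn.Conv2d(4 * f, n_classes, 3, rng=rng)
        self.n_classes = n_classes

    def prob_map(self, x: Tensor) -> Tensor:
        """Per-position class probabilities (B, N+1, H/8, W/8)."""
        return ag.softmax(self.head(self.features(x)), axis=1)

    def forward(self, x: Tensor) -> Tensor:
        """Return patch-averaged class probabilities (B, N+1)."""
        return ag.global_avg_pool(self.prob_map(x))


class _EncDec(Generator):
    def __init__(self, encoder: Encoder, decoder: Decoder):
        self.encoder = encoder
        self.decoder = decoder

    def forward(self, x: Tensor) -> Tensor:
        return self.decoder(self.encoder(x))


class NetworkBundle:
    """The six networks of the framework plus the region count they serve.

    ``ES``/``ET`` are the domain encoders, ``US``/``UT`` the decoders,
    ``DS``/``DT`` the discriminators.  Translation source -> target is
    ``UT(ES(x))``; target -> source is ``US(ET(x))``.
    """

    def __init__(self, ES: Encoder, ET: Encoder, US: Decoder, UT: Decoder,
                 DS: Discriminator, DT: Discriminator, n_regions: int,
                 source_channels: int, target_channels: int, width: WidthConfig):
        self.ES, self.ET, self.US, self.UT = ES, ET, US, UT
        self.DS, self.DT = DS, DT
        self.n_regions = n_regions
        self.source_channels = source_channels
        self.target_channels = target_channels
        self.width = width

    # ---------------------------------------------------------- composition
    def translate_st(self, s: Tensor) -> Tensor:
        return self.UT(self.ES(s))

    def translate_ts(self, t: Tensor) -> Tensor:
        return self.US(self.ET(t))

    def generator_st(self) -> Generator:
        return _EncDec(self.ES, self.UT)

    def generator_ts(self) -> Generator:
        return _EncDec(self.ET, self.US)

    def generator_parameters(self) -> list[nn.Parameter]:
        out = []
        for net in (self.ES, self.ET, self.US, self.UT):
            out.extend(net.parameters())
        return out

    def discriminator_parameters(self) -> list[nn.Parameter]:
        return self.DS.parameters() + self.DT.parameters()

    def generators(self):
        return (self.ES, self.ET, self.US, self.UT)

    def discriminators(self):
        return (self.DS, self.DT)

    def zero_grad(self) -> None:
        for net in (*self.generators(), *self.discriminators()):
            net.zero_grad()

    # -------------------------------------------------------- serialisation
    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, net in zip(("ES", "ET", "US", "UT", "DS", "DT"),
                             (*self.generators(), *self.discriminators())):
            for k, v in net.state_dict().items():
                out[f"{name}.{k}"] = v
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, net in zip(("ES", "ET", "US", "UT", "DS", "DT"),
                             (*self.generators(), *self.discriminators())):
            prefix = name + "."
            sub = {k[len(prefix):]: v for k, v in state.items() if k.startswith(prefix)}
            net.load_state_dict(sub)


def build_networks(
    source_channels: int,
    target_channels: int,
    n_regions: int,
    width: WidthConfig | None = None,
    seed: int = 0,
) -> NetworkBundle:
    """Construct the six-network bundle for N regions.

    The discriminator heads have exactly ``n_regions + 1`` output nodes: one
    per real region class and one node shared by all fake patches.
    """
    width = width or WidthConfig()
    if n_regions < 1:
        raise ContractError(f"n_regions must be >= 1, got {n_regions}")
    if source_channels < 1 or target_channels < 1:
        raise ContractError("channel counts must be >= 1")
    if n_regions + 1 > width.head_cap:
        raise MemoryFloorError(
            f"head width {n_regions + 1} exceeds cap {width.head_cap}; "
            "raise the tolerance lower bound to reduce the region count"
        )
    rng = np.random.default_rng(seed)
    ES = Encoder(source_channels, width, rng)
    ET = Encoder(target_channels, width, rng)
    US = Decoder(source_channels, width, rng)
    UT = Decoder(target_channels, width, rng)
    DS = Discriminator(source_channels, n_regions + 1, width, rng)
    DT = Discriminator(target_channels, n_regions + 1, width, rng)
    return NetworkBundle(ES, ET, US, UT, DS, DT, n_regions,
                         source_channels, target_channels, width)
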