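"""Run configuration shared by the command-line subcommands.

One YAML file drives the whole tolerance -> train -> translate pipeline.
Every key has a default taken from the reference training protocol
(lambda1 = lambda2 = 10, overlap 64, batch 2, 80 epochs, Adam at 2e-4);
unknown keys are rejected by name so typos cannot silently fall back to a
default.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ContractError
from .losses import LossWeights
from .networks import WidthConfig
from .training import TrainConfig

__all__ = ["RunConfig", "parse_config"]


@dataclass
class RunConfig:
    # loss weights
    lambda1: float = 10.0
    lambda2: float = 10.0
    lambda3: float = 0.01  # accepted for compatibility; enters no loss term
    # geometry
    overlap: int = 64
    patch_size: int = 256
    tile: int = 256
    # optimisation
    batch_size: int = 2
    epochs: int = 80
    base_lr: float = 2e-4
    decay_start: int = 41
    iterations_per_epoch: int | None = None
    checkpoint_every: int = 20
    seed: int = 0
    # sampling rule
    histogram_bins: int = 64
    # tolerance search
    tolerance: int | None = None  # fixed tolerance; None -> optimize
    tolerance_lower: int = 256
    tolerance_upper: int = 4096
    num_sampling: int = 64
    head_cap: int = 4096
    # architecture
    base_filters: int = 32
    n_res: int = 4

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            iterations_per_epoch=self.iterations_per_epoch,
            batch_size=self.batch_size,
            base_lr=self.base_lr,
            decay_start=self.decay_start,
            seed=self.seed,
            patch_size=self.patch_size,
            weights=LossWeights(self.lambda1, self.lambda2, self.lambda3),
            checkpoint_every=self.checkpoint_every,
            histogram_bins=self.histogram_bins,
        )

    def width_config(self) -> WidthConfig:
        return WidthConfig(
            base_filters=self.base_filters, n_res=self.n_res, head_cap=self.head_cap
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def parse_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run configuration.

    A missing path or empty file yields the full default configuration.
    Unknown keys raise :class:`ContractError` naming the offending key.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ContractError("config file must contain a mapping at top level")
    known = {f.name for f in fields(RunConfig)}
    for key in raw:
        if key not in known:
            raise ContractError(f"unknown config key {key!r}")
    cfg = RunConfig(**raw)
    if cfg.epochs < 1 or cfg.batch_size < 1 or cfg.base_lr <= 0:
        raise ContractError("epochs/batch_size/base_lr out of range")
    return cfg
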