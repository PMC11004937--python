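"""Alternating adversarial training with sampling-driven batching.

Each iteration draws a batch of roughly paired patches through the global
sampling rule, applies one discriminator update (minimising L_d = CE_d on
real-region and fake classes) and one generator update (minimising
L_g = CE_g + lambda1*L_cycle + lambda2*L_rec).  The learning rate is held at
``base_lr`` for the first ``decay_start`` epochs and decays linearly to zero
at the final epoch.  Runs are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .data import ImagePair
from .errors import ContractError
from .losses import LossWeights, cross_entropy_from_probs
from .networks import NetworkBundle, WidthConfig, build_networks
from .nn import Adam, Conv2d, Linear
from .nn import autograd as ag
from .nn.autograd import Tensor, no_grad
from .regions import RegionGrid, compute_sampling_distribution, sample_patch_pair

__all__ = [
    "TrainConfig",
    "TrainResult",
    "init_weights",
    "lr_at_epoch",
    "train",
    "train_with_restarts",
    "train_l1_baseline",
    "save_checkpoint",
    "load_checkpoint",
]

_DISC_INIT_SD = 0.02


@dataclass
class TrainConfig:
    """Optimization settings.

    Defaults follow the reference protocol: 80 epochs, batch size 2, Adam at
    2e-4 held for 40 epochs then linearly decayed to zero, loss weights
    lambda1 = lambda2 = 10.  ``iterations_per_epoch`` defaults to the total
    image area divided by the patch area, so one epoch sees roughly every
    pixel once.
    """

    epochs: int = 80
    iterations_per_epoch: int | None = None
    batch_size: int = 2
    base_lr: float = 2e-4
    decay_start: int = 41
    seed: int = 0
    patch_size: int = 256
    weights: LossWeights = field(default_factory=LossWeights)
    checkpoint_every: int = 20
    histogram_bins: int = 64
    adam_betas: tuple[float, float] = (0.5, 0.999)

    def __post_init__(self):
        if self.epochs < 1:
            raise ContractError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ContractError("batch_size must be >= 1")
        if self.base_lr <= 0:
            raise ContractError("base_lr must be > 0")
        if self.decay_start < 0:
            raise ContractError("decay_start must be >= 0")
        # decay_start beyond the final epoch simply means the rate never decays


@dataclass
class TrainResult:
    bundle: NetworkBundle
    history: dict[str, list[float]]
    config: TrainConfig


def lr_at_epoch(epoch: int, cfg: TrainConfig) -> float:
    """Learning rate for a given (0-based) epoch index.

    Constant at ``base_lr`` for epochs below ``decay_start``, then linear
    from ``base_lr`` at epoch ``decay_start - 1`` down to 0 at ``epochs``.
    """
    if not 0 <= epoch <= cfg.epochs:
        raise ContractError(f"epoch {epoch} outside [0, {cfg.epochs}]")
    if epoch < cfg.decay_start:
        return cfg.base_lr
    span = cfg.epochs - (cfg.decay_start - 1)
    return cfg.base_lr * (cfg.epochs - epoch) / span


def init_weights(bundle: NetworkBundle, rng: np.random.Generator) -> NetworkBundle:
    """Apply the initialisation policy in place and return the bundle.

    Generator conv/linear weights: Kaiming normal, std = sqrt(2 / fan_in)
    (preserving forward variance).  Discriminator weights: Normal(0, 0.02).
    Every bias is set to exactly zero.
    """
    for net in bundle.generators():
        for mod in net.modules():
            if isinstance(mod, (Conv2d, Linear)):
                std = float(np.sqrt(2.0 / mod.fan_in))
                mod.weight.data = rng.normal(0.0, std, mod.weight.data.shape).astype(
                    np.float32
                )
                if mod.bias is not None:
                    mod.bias.data = np.zeros_like(mod.bias.data)
    for net in bundle.discriminators():
        for mod in net.modules():
            if isinstance(mod, (Conv2d, Linear)):
                mod.weight.data = rng.normal(
                    0.0, _DISC_INIT_SD, mod.weight.data.shape
                ).astype(np.float32)
                if mod.bias is not None:
                    mod.bias.data = np.zeros_like(mod.bias.data)
    return bundle


# ---------------------------------------------------------------- batching
def _patch_to_chw(patch: np.ndarray) -> np.ndarray:
    a = np.asarray(patch, dtype=np.float32)
    if a.ndim == 2:
        return a[None]
    return a.transpose(2, 0, 1)


def _draw_batch(pairs, dists, grid, cfg, rng):
    s_list, t_list, labels = [], [], []
    for _ in range(cfg.batch_size):
        idx = int(rng.integers(len(pairs))) if len(pairs) > 1 else 0
        sp, tp, k = sample_patch_pair(
            pairs[idx].source, pairs[idx].target, grid, dists[idx], cfg.patch_size, rng
        )
        s_list.append(_patch_to_chw(sp))
        t_list.append(_patch_to_chw(tp))
        labels.append(k)
    return np.stack(s_list), np.stack(t_list), np.asarray(labels, dtype=np.int64)


def _l1(a: Tensor, b: Tensor) -> Tensor:
    return ag.mean(ag.absolute(a - b))


def _check_finite(name: str, value: float) -> float:
    if not np.isfinite(value):
        raise ContractError(f"non-finite loss term {name} = {value}; aborting training")
    return float(value)


def _train_step(bundle, opt_g, opt_d, s, t, labels, weights):
    """One discriminator update followed by one generator update."""
    n = bundle.n_regions
    fake_label = np.full(labels.shape, n, dtype=np.int64)
    s_t, t_t = Tensor(s), Tensor(t)

    # Generator forward pass with shared subexpressions; built once and used
    # by both updates (the discriminator step sees the fakes detached, and
    # does not change generator parameters, so the activations stay valid).
    es, et = bundle.ES(s_t), bundle.ET(t_t)
    l_rec = _l1(bundle.US(es), s_t) + _l1(bundle.UT(et), t_t)
    gen_t = bundle.UT(es)
    gen_s = bundle.US(et)
    l_cyc = _l1(bundle.US(bundle.ET(gen_t)), s_t) + _l1(bundle.UT(bundle.ES(gen_s)), t_t)

    dt = getattr(bundle.DT, "prob_map", bundle.DT)
    ds = getattr(bundle.DS, "prob_map", bundle.DS)
    # --- discriminator update (generated patches detached)
    ce_d = (
        cross_entropy_from_probs(dt(t_t), labels)
        + cross_entropy_from_probs(ds(s_t), labels)
        + cross_entropy_from_probs(dt(gen_t.detach()), fake_label)
        + cross_entropy_from_probs(ds(gen_s.detach()), fake_label)
    )
    bundle.zero_grad()
    ce_d.backward()
    opt_d.step()

    # --- generator update; the adversarial term sees the just-updated
    # discriminators, and its gradient flows through them into the
    # generators without touching discriminator parameters.
    ce_g = cross_entropy_from_probs(dt(gen_t), labels) + cross_entropy_from_probs(
        ds(gen_s), labels
    )
    lg = ce_g + weights.lambda1 * l_cyc + weights.lambda2 * l_rec
    bundle.zero_grad()
    lg.backward()
    opt_g.step()

    return {
        "Lg": _check_finite("Lg", float(lg.data)),
        "Ld": _check_finite("Ld", float(ce_d.data)),
        "CEg": _check_finite("CEg", float(ce_g.data)),
        "CEd": _check_finite("CEd", float(ce_d.data)),
        "Lcycle": _check_finite("Lcycle", float(l_cyc.data)),
        "Lrec": _check_finite("Lrec", float(l_rec.data)),
    }


def _default_iterations(pairs, cfg) -> int:
    total = sum(p.image_shape[0] * p.image_shape[1] for p in pairs)
    return max(1, -(-total // (cfg.patch_size**2)))


def train(
    pairs: list[ImagePair],
    grid: RegionGrid,
    cfg: TrainConfig,
    width: WidthConfig | None = None,
    checkpoint_dir: str | Path | None = None,
    resume_from: str | Path | None = None,
    log=None,
) -> TrainResult:
    """Train the full bundle on roughly paired images.

    The sampling distribution of every pair is computed once at start (it
    depends only on the data).  Checkpoints are written every
    ``checkpoint_every`` epochs when ``checkpoint_dir`` is given; passing the
    latest checkpoint as ``resume_from`` continues the identical trajectory.
    """
    if not pairs:
        raise ContractError("at least one image pair is required")
    for p in pairs:
        if p.image_shape != grid.image_shape:
            raise ContractError(
                f"pair shape {p.image_shape} does not match grid {grid.image_shape}"
            )
    width = width or WidthConfig()
    dists = [
        compute_sampling_distribution(
            p.source, p.target, grid, bins=cfg.histogram_bins, value_range=p.value_range
        )
        for p in pairs
    ]
    iters = cfg.iterations_per_epoch or _default_iterations(pairs, cfg)

    if resume_from is not None:
        bundle, opt_g, opt_d, rng, history, start_epoch = load_checkpoint(
            resume_from, pairs[0].source_channels, pairs[0].target_channels, cfg, width
        )
    else:
        rng = np.random.default_rng(cfg.seed)
        bundle = build_networks(
            pairs[0].source_channels,
            pairs[0].target_channels,
            grid.n_regions,
            width,
            seed=cfg.seed,
        )
        init_weights(bundle, rng)
        opt_g = Adam(bundle.generator_parameters(), cfg.base_lr, cfg.adam_betas)
        opt_d = Adam(bundle.discriminator_parameters(), cfg.base_lr, cfg.adam_betas)
        history = {
            k: [] for k in ("epoch", "iteration", "lr", "Lg", "Ld", "CEg", "CEd", "Lcycle", "Lrec")
        }
        start_epoch = 0

    for epoch in range(start_epoch, cfg.epochs):
        lr = lr_at_epoch(epoch, cfg)
        opt_g.set_lr(lr)
        opt_d.set_lr(lr)
        for it in range(iters):
            s, t, labels = _draw_batch(pairs, dists, grid, cfg, rng)
            terms = _train_step(bundle, opt_g, opt_d, s, t, labels, cfg.weights)
            history["epoch"].append(epoch)
            history["iteration"].append(epoch * iters + it)
            history["lr"].append(lr)
            for k, v in terms.items():
                history[k].append(v)
            if log is not None:
                log(
                    f"epoch={epoch} iter={it} lr={lr:.2e} "
                    + " ".join(f"{k}={v:.4f}" for k, v in terms.items())
                )
        if checkpoint_dir is not None and (
            (epoch + 1) % cfg.checkpoint_every == 0 or epoch + 1 == cfg.epochs
        ):
            save_checkpoint(
                Path(checkpoint_dir) / f"checkpoint_epoch{epoch + 1:04d}.npz",
                bundle,
                opt_g,
                opt_d,
                rng,
                history,
                epoch + 1,
                cfg,
            )
    return TrainResult(bundle=bundle, history=history, config=cfg)


def roughly_paired_agreement(
    output: np.ndarray,
    delivered: np.ndarray,
    block: int = 64,
    margin: int = 40,
) -> float:
    """Shift-tolerant agreement between a translation and the rough target.

    The delivered target of roughly paired data is displaced patchwise, so a
    pixelwise score against it is uninformative.  Instead each ``block`` of
    the delivered target is matched against a ``margin``-expanded window of
    the output by normalised cross-correlation and the per-block maxima are
    averaged: a correct translation finds its displaced counterpart nearby
    (score near 1), a collapsed or polarity-flipped one does not.  Uses only
    training-visible data — never the aligned ground truth.
    """
    from skimage.feature import match_template

    o = np.asarray(output, dtype=np.float64)
    d = np.asarray(delivered, dtype=np.float64)
    o = o.mean(axis=-1) if o.ndim == 3 else o
    d = d.mean(axis=-1) if d.ndim == 3 else d
    h, w = o.shape
    scores = []
    for r in range(0, h - block + 1, block):
        for c in range(0, w - block + 1, block):
            template = d[r : r + block, c : c + block]
            if template.std() == 0:
                continue
            window = o[
                max(0, r - margin) : min(h, r + block + margin),
                max(0, c - margin) : min(w, c + block + margin),
            ]
            if window.std() == 0:
                scores.append(0.0)
                continue
            scores.append(float(match_template(window, template).max()))
    return float(np.mean(scores)) if scores else 0.0


def _score_bundle(bundle: NetworkBundle, pair: ImagePair) -> float:
    from .inference import translate_tiled  # local import: avoids a cycle

    out = translate_tiled(
        pair.source, bundle, direction="st", tile=max(pair.image_shape)
    )
    return roughly_paired_agreement(out, pair.target)


def train_with_restarts(
    pairs: list[ImagePair],
    grid: RegionGrid,
    cfg: TrainConfig,
    width: WidthConfig | None = None,
    max_restarts: int = 5,
    probe_epochs: int = 3,
    accept_score: float = 0.7,
    snapshot_every: int = 2,
    log=None,
) -> TrainResult:
    """Train with validation-selected restarts and best-snapshot selection.

    At desk scale the adversarial game is seed-sensitive: some runs settle
    into a sign-flipped or collapsed equilibrium, and collapse can also
    occur late.  This wrapper (a) runs short probes (``probe_epochs``
    epochs) from seeds derived from ``cfg.seed`` and keeps the first whose
    :func:`roughly_paired_agreement` with the delivered target reaches
    ``accept_score`` (falling back to the best probe seen), then (b) trains
    the selected seed for the full budget, scoring a snapshot every
    ``snapshot_every`` epochs and returning the best-scoring parameters.
    Both selections use only training-visible data, never ground truth.
    """
    if probe_epochs >= cfg.epochs:
        raise ContractError("probe_epochs must be smaller than the epoch budget")
    best_seed, best_probe = None, -np.inf
    for attempt in range(max_restarts):
        seed_k = int((cfg.seed + 99_991 * attempt) % (2**31))
        probe_cfg = replace(cfg, seed=seed_k, epochs=probe_epochs)
        probe = train(pairs, grid, probe_cfg, width=width, log=log)
        score = _score_bundle(probe.bundle, pairs[0])
        if log is not None:
            log(f"probe attempt={attempt} seed={seed_k} agreement={score:+.3f}")
        if score > best_probe:
            best_seed, best_probe = seed_k, score
        if score >= accept_score:
            break

    # one full run writing periodic checkpoints, then keep the snapshot with
    # the best rough-target agreement
    import tempfile

    final_cfg = replace(cfg, seed=best_seed, checkpoint_every=snapshot_every)
    with tempfile.TemporaryDirectory(prefix="uframe_snap_") as tmpdir:
        result = train(pairs, grid, final_cfg, width=width,
                       checkpoint_dir=tmpdir, log=log)
        best_state = result.bundle.state_dict()
        best_score = _score_bundle(result.bundle, pairs[0])
        for ckpt in sorted(Path(tmpdir).glob("checkpoint_epoch*.npz")):
            snapshot, *_ = load_checkpoint(
                ckpt,
                pairs[0].source_channels,
                pairs[0].target_channels,
                final_cfg,
                width,
            )
            score = _score_bundle(snapshot, pairs[0])
            if log is not None:
                log(f"snapshot {ckpt.name} agreement={score:+.3f}")
            if score > best_score:
                best_state, best_score = snapshot.state_dict(), score
    result.bundle.load_state_dict(best_state)
    return result


# ------------------------------------------------------------- checkpoints
_CKPT_VERSION = 1


def save_checkpoint(path, bundle, opt_g, opt_d, rng, history, next_epoch, cfg) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    for k, v in bundle.state_dict().items():
        arrays[f"net::{k}"] = v
    for name, opt in (("g", opt_g), ("d", opt_d)):
        st = opt.state_dict()
        for i, (m, v) in enumerate(zip(st["m"], st["v"])):
            arrays[f"adam_{name}::m{i}"] = m
            arrays[f"adam_{name}::v{i}"] = v
    meta = {
        "version": _CKPT_VERSION,
        "next_epoch": int(next_epoch),
        "n_regions": bundle.n_regions,
        "source_channels": bundle.source_channels,
        "target_channels": bundle.target_channels,
        "adam_t": {"g": opt_g.t, "d": opt_d.t},
        "adam_lr": {"g": opt_g.lr, "d": opt_d.lr},
        "rng_state": rng.bit_generator.state,
        "history": history,
        "weights": asdict(cfg.weights),
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path, source_channels, target_channels, cfg, width):
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"].tobytes()).decode())
        net_state = {
            k.split("::", 1)[1]: data[k] for k in data.files if k.startswith("net::")
        }
        adam_arrays = {
            name: {
                "m": [data[k] for k in sorted((f for f in data.files if f.startswith(f"adam_{name}::m")), key=lambda s: int(s.rsplit("m", 1)[1]))],
                "v": [data[k] for k in sorted((f for f in data.files if f.startswith(f"adam_{name}::v")), key=lambda s: int(s.rsplit("v", 1)[1]))],
            }
            for name in ("g", "d")
        }
    bundle = build_networks(
        source_channels, target_channels, meta["n_regions"], width, seed=cfg.seed
    )
    bundle.load_state_dict(net_state)
    opt_g = Adam(bundle.generator_parameters(), cfg.base_lr, cfg.adam_betas)
    opt_d = Adam(bundle.discriminator_parameters(), cfg.base_lr, cfg.adam_betas)
    for name, opt in (("g", opt_g), ("d", opt_d)):
        opt.load_state_dict(
            {
                "t": meta["adam_t"][name],
                "lr": meta["adam_lr"][name],
                "m": adam_arrays[name]["m"],
                "v": adam_arrays[name]["v"],
            }
        )
    rng = np.random.default_rng()
    rng.bit_generator.state = meta["rng_state"]
    return bundle, opt_g, opt_d, rng, meta["history"], meta["next_epoch"]


# ----------------------------------------------------- supervised ablation
def train_l1_baseline(
    pairs: list[ImagePair],
    cfg: TrainConfig,
    width: WidthConfig | None = None,
):
    """Pixelwise-supervised ablation: one source->target generator under L1.

    Patches are cropped at the *same* position in source and target (full
    pixelwise supervision on the delivered pairing) and the generator
    minimises mean |G(s) - t| with the identical optimizer, schedule and
    iteration budget as :func:`train`.  Used as the supervised reference
    point in evaluations.
    """
    if not pairs:
        raise ContractError("at least one image pair is required")
    width = width or WidthConfig()
    rng = np.random.default_rng(cfg.seed)
    bundle = build_networks(
        pairs[0].source_channels, pairs[0].target_channels, 1, width, seed=cfg.seed
    )
    init_weights(bundle, rng)
    gen = bundle.generator_st()
    opt = Adam(gen.parameters(), cfg.base_lr, cfg.adam_betas)
    iters = cfg.iterations_per_epoch or _default_iterations(pairs, cfg)
    history: dict[str, list[float]] = {"L1": [], "lr": []}
    ps = cfg.patch_size
    for epoch in range(cfg.epochs):
        lr = lr_at_epoch(epoch, cfg)
        opt.set_lr(lr)
        for _ in range(iters):
            s_list, t_list = [], []
            for _ in range(cfg.batch_size):
                idx = int(rng.integers(len(pairs))) if len(pairs) > 1 else 0
                p = pairs[idx]
                h, w = p.image_shape
                r = int(rng.integers(0, h - ps + 1))
                c = int(rng.integers(0, w - ps + 1))
                s_list.append(_patch_to_chw(p.source[r : r + ps, c : c + ps]))
                t_list.append(_patch_to_chw(p.target[r : r + ps, c : c + ps]))
            s_t, t_t = Tensor(np.stack(s_list)), Tensor(np.stack(t_list))
            loss = _l1(gen(s_t), t_t)
            gen.zero_grad()
            loss.backward()
            opt.step()
            history["L1"].append(_check_finite("L1", float(loss.data)))
            history["lr"].append(lr)
    return gen, history
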