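"""The four training losses.

Generators minimise  L_g = CE_g + lambda1 * L_cycle + lambda2 * L_rec,
discriminators minimise  L_d = CE_d.

* L_rec  — L1 between each input and its own-domain reconstruction
  US(ES(s)), UT(ET(t)).
* L_cycle — L1 round-trip consistency US(ET(UT(ES(s)))) vs s and the
  reverse direction.
* CE_d — cross-entropy pushing discriminators to put real patches on their
  region class and generated patches on the shared fake class (index N).
* CE_g — cross-entropy pushing generated patches toward the *region class*
  of the patch they were generated from, i.e. the generator wins by making
  fakes indistinguishable from that region's real patches.

L1 terms are means over batch, pixels and channels (the plain summed form is
this mean times batch*pixels*channels), so the default weights keep their
meaning across patch sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .networks import NetworkBundle
from .nn import autograd as ag
from .nn.autograd import Tensor

__all__ = [
    "LossWeights",
    "reconstruction_loss",
    "cycle_loss",
    "adversarial_ce",
    "total_losses",
    "cross_entropy_from_probs",
    "EPS",
]

EPS = 1e-12  # floor under log() in the cross-entropy terms


@dataclass(frozen=True)
class LossWeights:
    """lambda1 weights the cycle loss, lambda2 the reconstruction loss.

    ``lambda3`` is accepted for config compatibility but enters no loss term.
    """

    lambda1: float = 10.0
    lambda2: float = 10.0
    lambda3: float = 0.01

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ContractError("loss weights must be nonnegative")


def _l1(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ContractError(f"shape mismatch in L1: {a.shape} vs {b.shape}")
    return ag.mean(ag.absolute(a - b))


def _as_batch(x) -> Tensor:
    t = ag.as_tensor(x)
    if t.ndim != 4:
        raise ContractError(f"expected a (B, C, H, W) batch, got shape {t.shape}")
    if t.data.shape[0] < 1:
        raise ContractError("batch is empty")
    return t


def reconstruction_loss(bundle: NetworkBundle, s, t) -> Tensor:
    """L1 self-reconstruction within each domain."""
    s, t = _as_batch(s), _as_batch(t)
    return _l1(bundle.US(bundle.ES(s)), s) + _l1(bundle.UT(bundle.ET(t)), t)


def cycle_loss(bundle: NetworkBundle, s, t) -> Tensor:
    """L1 round-trip consistency through the opposite domain and back."""
    s, t = _as_batch(s), _as_batch(t)
    forward = _l1(bundle.US(bundle.ET(bundle.UT(bundle.ES(s)))), s)
    backward = _l1(bundle.UT(bundle.ES(bundle.US(bundle.ET(t)))), t)
    return forward + backward


def cross_entropy_from_probs(probs: Tensor, labels: np.ndarray) -> Tensor:
    """Mean -log p[label] over a batch of probability vectors or maps.

    Accepts (B, C) probability vectors or (B, C, H, W) per-position
    probability maps from a patch-level discriminator head; maps average the
    cross-entropy over all spatial positions.
    """
    labels = np.asarray(labels, dtype=np.int64)
    n_classes = probs.shape[1] if probs.ndim == 4 else probs.shape[-1]
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ContractError(
            f"label out of range [0, {n_classes - 1}]: {labels.min()}..{labels.max()}"
        )
    if probs.ndim == 2:
        return ag.mean(-ag.log(ag.gather_rows(probs, labels), eps=EPS))
    onehot = np.zeros((labels.size, n_classes, 1, 1), dtype=probs.data.dtype)
    onehot[np.arange(labels.size), labels, 0, 0] = 1.0
    # masked mean over B*C*H*W keeps one term per position; rescale by C
    return ag.mean(ag.mul(-ag.log(probs, eps=EPS), Tensor(onehot))) * float(n_classes)


def adversarial_ce(
    bundle: NetworkBundle,
    s,
    s_labels: np.ndarray,
    t,
    t_labels: np.ndarray,
) -> tuple[Tensor, Tensor]:
    """Return (CE_g, CE_d) for one batch with region labels.

    The fake class index is N.  The discriminator loss sees generated
    patches through ``detach`` so no gradient reaches the generators; the
    generator loss backpropagates through the discriminators into the
    generators (the training loop simply never applies discriminator
    parameter updates from it).
    """
    s, t = _as_batch(s), _as_batch(t)
    s_labels = np.asarray(s_labels, dtype=np.int64)
    t_labels = np.asarray(t_labels, dtype=np.int64)
    n = bundle.n_regions
    if s_labels.max() >= n or t_labels.max() >= n or s_labels.min() < 0 or t_labels.min() < 0:
        raise ContractError(f"region labels must lie in [0, {n - 1}]")
    fake_s = np.full(s_labels.shape, n, dtype=np.int64)
    fake_t = np.full(t_labels.shape, n, dtype=np.int64)

    gen_t = bundle.UT(bundle.ES(s))  # fake target from source patch
    gen_s = bundle.US(bundle.ET(t))  # fake source from target patch

    dt = getattr(bundle.DT, "prob_map", bundle.DT)
    ds = getattr(bundle.DS, "prob_map", bundle.DS)
    ce_d = (
        cross_entropy_from_probs(dt(t), t_labels)
        + cross_entropy_from_probs(ds(s), s_labels)
        + cross_entropy_from_probs(dt(gen_t.detach()), fake_t)
        + cross_entropy_from_probs(ds(gen_s.detach()), fake_s)
    )
    ce_g = (
        cross_entropy_from_probs(dt(gen_t), s_labels)
        + cross_entropy_from_probs(ds(gen_s), t_labels)
    )
    return ce_g, ce_d


def total_losses(ce_g, ce_d, l_cycle, l_rec, w: LossWeights) -> tuple[Tensor, Tensor]:
    """Combine components: L_g = CE_g + l1*L_cycle + l2*L_rec; L_d = CE_d."""
    for name, v in (("CEg", ce_g), ("CEd", ce_d), ("Lcycle", l_cycle), ("Lrec", l_rec)):
        data = v.data if isinstance(v, Tensor) else np.asarray(v)
        if not np.all(np.isfinite(data)):
            raise ContractError(f"non-finite loss component {name}")
    lg = ag.as_tensor(ce_g) + w.lambda1 * ag.as_tensor(l_cycle) + w.lambda2 * ag.as_tensor(l_rec)
    return lg, ag.as_tensor(ce_d)
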