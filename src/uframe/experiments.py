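"""Frozen desk-scale benchmark recipes.

Each function builds its synthetic study conditions, runs the method end to
end and returns the measured quantities.  The conditions (image and cell
sizes, appearance mapping, misalignment, noise, network preset, iteration
budget) are fixed here so that the test suite, the acceptance script and the
examples all exercise exactly the same protocol; only the base seed varies.

Scale rationale: the full protocol (32-filter networks, 80 epochs,
full-resolution micrographs) is far beyond a single-CPU run, so the
benchmarks use the tiny network preset on 256-px images with 64-px patches,
N = 4 regions and a few hundred iterations at a proportionally raised
learning rate; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ImagePair
from .inference import ms_ssim, translate_tiled
from .networks import WidthConfig
from .preprocess import sobel_channels
from .regions import partition_regions
from .synthetic import SyntheticSpec, generate_dataset, regionwise_paired_spec
from .tolerance import ToleranceSearchConfig, optimize_tolerance
from .training import TrainConfig, train_l1_baseline, train_with_restarts

__all__ = [
    "TrainingBenchmark",
    "training_spec",
    "training_config",
    "network_ready_source",
    "aligned_translation_benchmark",
    "misalignment_comparison_benchmark",
    "tolerance_recovery_benchmark",
]

# -- frozen study conditions -------------------------------------------------
_IMAGE = 256
_CELL = 64
_TOLERANCE = 128  # N = 4 regions on a 256-px image
_PATCH = 64
_OVERLAP = 64
_EPOCHS = 15
_ITERS_PER_EPOCH = 40  # 600 iterations total; probes span 2 epochs (80)
_LR = 2e-3  # desk-scale rate; full-scale default remains 2e-4
_APPEARANCE = "hema-mix"  # 1 -> 3 channels, the virtual-staining regime


def training_spec(seed: int, misalign_d: float = 0.0) -> SyntheticSpec:
    """Synthetic acquisition used by the training benchmarks."""
    return SyntheticSpec(
        image_size=_IMAGE,
        cell_size=_CELL,
        appearance=_APPEARANCE,
        misalign_mode="displace",
        misalign_d=misalign_d,
        jitter_shift=0.0,
        jitter_rotation=0.0,
        jitter_scale=0.0,
        noise_sigma=0.01,
        seed=seed,
    )


def training_config(seed: int) -> TrainConfig:
    return TrainConfig(
        epochs=_EPOCHS,
        iterations_per_epoch=_ITERS_PER_EPOCH,
        batch_size=2,
        base_lr=_LR,
        decay_start=_EPOCHS + 1,  # constant rate over the short budget
        seed=seed,
        patch_size=_PATCH,
    )


@dataclass
class TrainingBenchmark:
    baseline_ms_ssim: float
    translated_ms_ssim: float

    @property
    def gain(self) -> float:
        return self.translated_ms_ssim - self.baseline_ms_ssim


def _replicate_channels(source: np.ndarray, n: int) -> np.ndarray:
    if source.ndim == 2 and n > 1:
        return np.repeat(source[:, :, None], n, axis=2)
    return source


def network_ready_source(source: np.ndarray) -> np.ndarray:
    """Single-channel source -> 3-channel network input [intensity, Gx, Gy].

    The standard input pipeline when a 1-channel source feeds a 3-channel
    target: the two Sobel-Feldman derivatives join the original channel.
    Returned in [0, 1] floats.
    """
    u8 = np.clip(np.round(np.asarray(source, dtype=np.float64) * 255), 0, 255).astype(
        np.uint8
    )
    return sobel_channels(u8).astype(np.float64) / 255.0


def _train_uframe(pair: ImagePair, seed: int):
    grid = partition_regions(pair.image_shape, _TOLERANCE, _OVERLAP, _PATCH)
    result = train_with_restarts(
        [pair], grid, training_config(seed), width=WidthConfig.tiny(), probe_epochs=2
    )
    return result.bundle


def aligned_translation_benchmark(seed: int = 0) -> TrainingBenchmark:
    """Train on pixel-aligned pairs; compare translation with ground truth.

    Returns the MS-SSIM of the translated source against the aligned target
    and the untranslated baseline (source replicated to the target's channel
    count).
    """
    data = generate_dataset(training_spec(seed, misalign_d=0.0))
    net_source = network_ready_source(data.source)
    pair = ImagePair(net_source, data.target)
    bundle = _train_uframe(pair, seed)
    out = translate_tiled(net_source, bundle, direction="st", tile=_IMAGE)
    nch = data.target_true.shape[-1] if data.target_true.ndim == 3 else 1
    baseline = ms_ssim(_replicate_channels(data.source, nch), data.target_true)
    return TrainingBenchmark(baseline, ms_ssim(out, data.target_true))


def misalignment_comparison_benchmark(
    seed: int = 0, n_seeds: int = 5, misalign_d: float = _PATCH / 2
):
    """Roughly paired training: region-tolerant GAN vs pixelwise-L1 ablation.

    Both models receive the identical Sobel-augmented source and train on
    the *delivered* (displaced) target with identical budgets; both are
    scored by MS-SSIM against the aligned ground truth.  Returns
    (uframe scores, l1 scores, wins) across ``n_seeds`` repeats.
    """
    uframe_scores, l1_scores = [], []
    for k in range(n_seeds):
        run_seed = int((seed + 1009 * k) % (2**31))
        data = generate_dataset(training_spec(run_seed, misalign_d=misalign_d))
        net_source = network_ready_source(data.source)
        pair = ImagePair(net_source, data.target)
        bundle = _train_uframe(pair, run_seed)
        out = translate_tiled(net_source, bundle, direction="st", tile=_IMAGE)
        uframe_scores.append(ms_ssim(out, data.target_true))

        gen, _ = train_l1_baseline([pair], training_config(run_seed), WidthConfig.tiny())
        l1_out = translate_tiled(net_source, gen, tile=_IMAGE)
        l1_scores.append(ms_ssim(l1_out, data.target_true))
    wins = sum(u >= l for u, l in zip(uframe_scores, l1_scores))
    return uframe_scores, l1_scores, wins


def tolerance_recovery_benchmark(seed: int = 0, n_seeds: int = 20, cell: int = 64):
    """Recover the texture cell size by the tolerance search.

    For each repeat a fresh regionwise-paired dataset is generated and the
    search scans {cell/4 ... 4*cell}; a hit is the true cell size or an
    adjacent candidate.  Returns (hits, n_seeds, chosen list).
    """
    chosen = []
    hits = 0
    for k in range(n_seeds):
        run_seed = int((seed + 7919 * k) % (2**31))
        data = generate_dataset(
            regionwise_paired_spec(cell_size=cell, image_size=512, seed=run_seed)
        )
        cfg = ToleranceSearchConfig(
            lower_bound=cell // 4, upper_bound=4 * cell, num_sampling=192, seed=run_seed
        )
        result = optimize_tolerance(data.source, data.target, cfg)
        chosen.append(result.tolerance)
        hits += result.tolerance in (cell // 2, cell, 2 * cell)
    return hits, n_seeds, chosen
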