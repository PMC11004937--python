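"""Initialisation policy, learning-rate schedule and the training loop."""

import numpy as np
import pytest
from scipy import stats

from uframe.data import ImagePair
from uframe.errors import ContractError
from uframe.losses import LossWeights, adversarial_ce
from uframe.networks import WidthConfig, build_networks
from uframe.nn import Adam, Conv2d, Linear
from uframe.regions import compute_sampling_distribution, partition_regions, sample_patch_pair
from uframe.training import (
    TrainConfig,
    init_weights,
    lr_at_epoch,
    train,
    train_l1_baseline,
)


def _short_cfg(**kw):
    base = dict(
        epochs=2,
        iterations_per_epoch=3,
        batch_size=2,
        patch_size=64,
        seed=0,
        decay_start=3,
        checkpoint_every=1,
    )
    base.update(kw)
    return TrainConfig(**base)


class TestSchedule:
    def test_paper_schedule_values(self):
        cfg = TrainConfig()
        assert lr_at_epoch(10, cfg) == pytest.approx(2e-4)
        assert lr_at_epoch(40, cfg) == pytest.approx(2e-4)
        assert lr_at_epoch(60, cfg) == pytest.approx(1e-4)
        assert lr_at_epoch(80, cfg) == 0.0

    def test_schedule_is_nonincreasing(self):
        cfg = TrainConfig()
        lrs = [lr_at_epoch(e, cfg) for e in range(81)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_epoch_out_of_range(self):
        with pytest.raises(ContractError):
            lr_at_epoch(81, TrainConfig())
        with pytest.raises(ContractError):
            lr_at_epoch(-1, TrainConfig())


class TestInit:
    def test_all_biases_zero(self):
        bundle = build_networks(1, 1, 4, WidthConfig.tiny(), seed=3)
        init_weights(bundle, np.random.default_rng(3))
        for net in (*bundle.generators(), *bundle.discriminators()):
            for mod in net.modules():
                if isinstance(mod, (Conv2d, Linear)) and mod.bias is not None:
                    assert (mod.bias.data == 0).all()

    def test_discriminator_weights_narrow_normal(self):
        bundle = build_networks(1, 1, 4, WidthConfig(base_filters=16, n_res=1), seed=0)
        init_weights(bundle, np.random.default_rng(0))
        w = np.concatenate(
            [
                mod.weight.data.ravel()
                for mod in bundle.DT.modules()
                if isinstance(mod, (Conv2d, Linear))
            ]
        )
        n = w.size
        assert n >= 10_000
        assert abs(w.mean()) < 3 * 0.02 / np.sqrt(n)
        assert abs(w.std() - 0.02) < 3 * 0.02 / np.sqrt(2 * n)

    def test_generator_kaiming_variance(self):
        bundle = build_networks(1, 1, 4, WidthConfig(base_filters=16, n_res=2), seed=1)
        init_weights(bundle, np.random.default_rng(1))
        for mod in bundle.ES.modules():
            if isinstance(mod, Conv2d) and mod.weight.data.size > 2000:
                var = mod.weight.data.var()
                assert abs(var - 2.0 / mod.fan_in) < 0.1 * (2.0 / mod.fan_in)


class TestLoop:
    def test_deterministic_given_seed(self, aligned_pair, four_region_grid, tiny_width):
        a = train([aligned_pair], four_region_grid, _short_cfg(), width=tiny_width)
        b = train([aligned_pair], four_region_grid, _short_cfg(), width=tiny_width)
        assert a.history["Lg"] == b.history["Lg"]
        sa, sb = a.bundle.state_dict(), b.bundle.state_dict()
        for k in sa:
            np.testing.assert_array_equal(sa[k], sb[k])

    def test_resume_reproduces_trajectory(self, aligned_pair, four_region_grid, tiny_width, tmp_path):
        full = train([aligned_pair], four_region_grid, _short_cfg(), width=tiny_width,
                     checkpoint_dir=tmp_path / "full")
        partial_cfg = _short_cfg(epochs=1)
        train([aligned_pair], four_region_grid, partial_cfg, width=tiny_width,
              checkpoint_dir=tmp_path / "part")
        resumed = train([aligned_pair], four_region_grid, _short_cfg(), width=tiny_width,
                        resume_from=tmp_path / "part" / "checkpoint_epoch0001.npz")
        assert resumed.history["Lg"] == full.history["Lg"]
        sa, sb = full.bundle.state_dict(), resumed.bundle.state_dict()
        for k in sa:
            np.testing.assert_array_equal(sa[k], sb[k])

    def test_history_finite_and_complete(self, aligned_pair, four_region_grid, tiny_width):
        res = train([aligned_pair], four_region_grid, _short_cfg(), width=tiny_width)
        for key in ("Lg", "Ld", "CEg", "CEd", "Lcycle", "Lrec", "lr"):
            vals = np.asarray(res.history[key])
            assert vals.shape == (6,)
            assert np.isfinite(vals).all()

    def test_geometry_mismatch_rejected(self, aligned_pair, tiny_width):
        grid = partition_regions((128, 128), 64, overlap=32, patch_size=64)
        with pytest.raises(ContractError):
            train([aligned_pair], grid, _short_cfg(), width=tiny_width)

    def test_discriminator_step_descends(self, aligned_pair, four_region_grid, tiny_width):
        """A small-lr discriminator update reduces L_d on the same batch."""
        dist = compute_sampling_distribution(
            aligned_pair.source, aligned_pair.target, four_region_grid
        )
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            bundle = build_networks(1, 1, 4, tiny_width, seed=seed)
            init_weights(bundle, rng)
            s_list, t_list, labels = [], [], []
            for _ in range(4):
                sp, tp, k = sample_patch_pair(
                    aligned_pair.source, aligned_pair.target, four_region_grid, dist, 64, rng
                )
                s_list.append(sp[None])
                t_list.append(tp[None])
                labels.append(k)
            s = np.stack(s_list).astype(np.float32)
            t = np.stack(t_list).astype(np.float32)
            labels = np.asarray(labels)
            opt = Adam(bundle.discriminator_parameters(), lr=1e-4)
            _, ce_d0 = adversarial_ce(bundle, s, labels, t, labels)
            bundle.zero_grad()
            ce_d0.backward()
            opt.step()
            _, ce_d1 = adversarial_ce(bundle, s, labels, t, labels)
            wins += float(ce_d1.data) < float(ce_d0.data)
        assert wins >= 18

    def test_region_exposure_matches_p(self, four_region_grid):
        """Sampled region labels over an epoch follow P (chi-square, alpha=0.01)."""
        rng = np.random.default_rng(11)
        img = rng.random((256, 256))
        dist = compute_sampling_distribution(img, img, four_region_grid)
        counts = np.zeros(4)
        n = 4000
        for _ in range(n):
            _, _, k = sample_patch_pair(img, img, four_region_grid, dist, 64, rng)
            counts[k] += 1
        _, p = stats.chisquare(counts, n * dist.P)
        assert p > 0.01

    def test_l1_baseline_trains_and_descends(self, aligned_pair, tiny_width):
        cfg = _short_cfg(epochs=1, iterations_per_epoch=40)
        gen, history = train_l1_baseline([aligned_pair], cfg, width=tiny_width)
        l1 = history["L1"]
        assert len(l1) == 40 and np.isfinite(l1).all()
        assert np.mean(l1[-10:]) < np.mean(l1[:10])
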