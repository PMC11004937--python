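"""Intensity scaling, Sobel channels and affine registration."""

import numpy as np
import pytest

from uframe.errors import ContractError, RankDeficiencyError, UndefinedCorrelationError
from uframe.preprocess import (
    LocalSearchConfig,
    affine_from_points,
    intensity_scale,
    refine_local_affine,
    sobel_channels,
    sobel_derivatives,
)


class TestIntensityScale:
    def test_constant_image_is_degenerate_passthrough(self):
        out, report = intensity_scale(np.full((32, 32), 3.7))
        assert report.degenerate
        np.testing.assert_array_equal(out, 0.0)

    def test_spikes_are_saturated(self, rng):
        img = rng.uniform(0, 1, 1_000_000)
        img[:100] = 10.0
        out, report = intensity_scale(img.reshape(1000, 1000))
        spikes = out.reshape(-1)[:100]
        np.testing.assert_array_equal(spikes, 1.0)
        # clip value sits in the top 0.1% neighbourhood of the uniform bulk
        assert 0.995 <= report.clip_value <= 10.0
        assert report.clip_value < 1.01

    def test_monotone_mapping(self, rng):
        img = rng.normal(10, 3, (64, 64))
        out, _ = intensity_scale(img)
        order = np.argsort(img.ravel())
        assert (np.diff(out.ravel()[order]) >= 0).all()

    def test_output_in_unit_interval_and_idempotent(self, rng):
        img = rng.gamma(2.0, 1.0, (128, 128))
        once, _ = intensity_scale(img)
        assert once.min() >= 0 and once.max() <= 1
        twice, _ = intensity_scale(once)
        assert np.abs(twice - once).max() < 1e-6

    def test_background_fence_reported(self, rng):
        img = np.concatenate([rng.normal(0.1, 0.02, 5000), rng.normal(0.9, 0.05, 5000)])
        _, report = intensity_scale(img.reshape(100, 100))
        assert report.otsu_threshold is not None
        assert report.background_fence is not None
        assert report.background_fence < report.otsu_threshold * 2


class TestSobel:
    def test_constant_image_maps_to_midrange(self):
        out = sobel_channels(np.full((16, 16), 0.5))
        assert out.shape == (16, 16, 3)
        np.testing.assert_array_equal(out[..., 1], 128)
        np.testing.assert_array_equal(out[..., 2], 128)

    def test_ramp_raw_derivative_is_kernel_weight_sum(self):
        ramp = np.tile(np.arange(16, dtype=np.float64), (16, 1))
        gx, gy = sobel_derivatives(ramp)
        np.testing.assert_array_equal(gx[1:-1, 1:-1], 8.0)
        np.testing.assert_array_equal(gy[1:-1, 1:-1], 0.0)

    def test_output_contract(self, rng):
        img = rng.random((33, 47))
        out = sobel_channels(img)
        assert out.shape == (33, 47, 3)
        assert out.dtype == np.uint8

    def test_multichannel_input_rejected(self, rng):
        with pytest.raises(ContractError):
            sobel_channels(rng.random((16, 16, 3)))


class TestAffineFromPoints:
    def test_identity(self, rng):
        pts = rng.uniform(0, 100, (8, 2))
        affine, report = affine_from_points(pts, pts)
        np.testing.assert_allclose(affine, [[1, 0, 0], [0, 1, 0]], atol=1e-12)
        assert report["rms"] < 1e-12

    def test_recovers_known_affine(self, rng):
        A = np.array([[0.9, -0.2, 5.0], [0.15, 1.1, -3.0]])
        src = rng.uniform(0, 50, (10, 2))
        dst = src @ A[:, :2].T + A[:, 2]
        est, report = affine_from_points(src, dst)
        np.testing.assert_allclose(est, A, atol=1e-10)
        assert report["rms"] <= 1e-10

    def test_collinear_points_rejected(self):
        src = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(RankDeficiencyError):
            affine_from_points(src, src)

    def test_too_few_points_rejected(self):
        with pytest.raises(RankDeficiencyError):
            affine_from_points(np.zeros((2, 2)), np.zeros((2, 2)))


class TestRefineLocalAffine:
    def _texture(self, rng, n=96):
        from scipy import ndimage

        img = ndimage.gaussian_filter(rng.normal(size=(n, n)), 2.0)
        return (img - img.min()) / (img.max() - img.min())

    def test_already_aligned(self, rng):
        img = self._texture(rng)
        patch = img[20:52, 30:62]
        init = np.array([[1.0, 0, 30.0], [0, 1.0, 20.0]])  # x, y offsets
        affine, corr = refine_local_affine(patch, img, init)
        assert corr >= 0.999
        np.testing.assert_allclose(affine[:, :2], init[:, :2], atol=0.05)

    def test_recovers_known_shift(self, rng):
        img = self._texture(rng)
        dx, dy = 3, -4
        patch = img[24 + dy : 56 + dy, 40 + dx : 72 + dx]
        init = np.array([[1.0, 0, 40.0], [0, 1.0, 24.0]])
        cfg = LocalSearchConfig(max_translation=8.0, initial_step=2.0)
        affine, corr = refine_local_affine(patch, img, init, cfg)
        assert corr > 0.98
        assert abs(affine[0, 2] - (40 + dx)) <= 1.0
        assert abs(affine[1, 2] - (24 + dy)) <= 1.0

    def test_constant_patch_rejected(self, rng):
        img = self._texture(rng)
        with pytest.raises(UndefinedCorrelationError):
            refine_local_affine(np.zeros((16, 16)), img, np.array([[1.0, 0, 0], [0, 1.0, 0]]))

    def test_never_worse_than_init(self, rng):
        from uframe.tolerance import pearson_correlation

        img = self._texture(rng)
        patch = img[10:42, 10:42]
        init = np.array([[1.0, 0, 12.0], [0, 1.0, 11.0]])  # slightly off
        _, corr = refine_local_affine(patch, img, init)
        # correlation at the (mis-set) init
        from uframe.preprocess import _sample_window

        window = _sample_window(img, init, patch.shape, (0, 0))
        init_corr = pearson_correlation(patch.ravel(), window.ravel())
        assert corr >= init_corr - 1e-12
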