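"""Region partition geometry and the global sampling rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uframe.errors import ContractError, InvalidGeometryError
from uframe.regions import (
    RegionGrid,
    compute_sampling_distribution,
    partition_regions,
    sample_patch_pair,
)


def brute_force_qp(source, target, grid, bins=64, value_range=(0.0, 1.0)):
    """Straight-line reimplementation of the printed Q_i / P_i formulas."""
    n = grid.n_regions
    H = np.zeros((n, bins))
    Q = np.zeros(n)
    for i, rect in enumerate(grid.regions):
        s = source[rect.r0 : rect.r1, rect.c0 : rect.c1].astype(np.float64).ravel()
        t = target[rect.r0 : rect.r1, rect.c0 : rect.c1].astype(np.float64).ravel()
        h, _ = np.histogram(s, bins=bins, range=value_range)
        H[i] = h / h.sum()
        if s.std() == 0 or t.std() == 0:
            corr = 0.0
        else:
            corr = np.cov(s, t, bias=True)[0, 1] / (s.std() * t.std())
        Q[i] = 1.0 + corr
    for i in range(n):
        denom = sum(float(H[i] @ H[j]) for j in range(n))
        Q[i] = Q[i] / denom
    return Q, Q / Q.sum()


@pytest.mark.parametrize(
    "shape,tol,expected_n,expected_rects",
    [
        ((1024, 1024), 512, 4, [(0, 0, 512, 512), (0, 512, 512, 1024), (512, 0, 1024, 512), (512, 512, 1024, 1024)]),
        ((1000, 1000), 512, 4, [(0, 0, 512, 512), (0, 512, 512, 1000), (512, 0, 1000, 512), (512, 512, 1000, 1000)]),
        ((512, 512), 512, 1, [(0, 0, 512, 512)]),
    ],
)
def test_partition_examples(shape, tol, expected_n, expected_rects):
    grid = partition_regions(shape, tol, overlap=64, patch_size=256)
    assert grid.n_regions == expected_n
    assert [r.as_tuple() for r in grid.regions] == expected_rects


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    h=st.integers(40, 300),
    w=st.integers(40, 300),
    tol=st.integers(8, 40),
)
def test_partition_coverage_and_exclusivity(h, w, tol):
    """Every pixel belongs to exactly one region, for arbitrary geometry."""
    grid = partition_regions((h, w), tol, overlap=0, patch_size=1)
    counts = np.zeros((h, w), dtype=int)
    for r in grid.regions:
        counts[r.r0 : r.r1, r.c0 : r.c1] += 1
    assert counts.min() == 1 and counts.max() == 1


def test_partition_expanded_regions_fit_patch():
    grid = partition_regions((256, 256), 64, overlap=32, patch_size=96)
    for i in range(grid.n_regions):
        exp = grid.expanded(i)
        assert exp.height >= 96 and exp.width >= 96


def test_partition_rejects_undersized_image():
    with pytest.raises(InvalidGeometryError):
        partition_regions((100, 100), 128, overlap=0, patch_size=32)
    with pytest.raises(InvalidGeometryError) as err:
        partition_regions((128, 128), 128, overlap=0, patch_size=256)
    assert "patch" in str(err.value)


def test_region_indices_row_major():
    grid = partition_regions((128, 192), 64, overlap=0, patch_size=32)
    assert grid.n_regions == 6
    assert grid.region_of(0, 0) == 0
    assert grid.region_of(0, 70) == 1
    assert grid.region_of(70, 0) == 3
    assert grid.region_of(127, 191) == 5


def test_grid_json_roundtrip():
    grid = partition_regions((200, 300), 100, overlap=16, patch_size=64)
    back = RegionGrid.from_json(grid.to_json())
    assert back == grid


def _four_constant_regions(values):
    img = np.zeros((8, 8))
    img[:4, :4] = values[0]
    img[:4, 4:] = values[1]
    img[4:, :4] = values[2]
    img[4:, 4:] = values[3]
    return img


def test_sampling_uniform_for_distinct_constant_regions():
    """Four constant regions with distinct values: Q = 1, P = 1/4 exactly."""
    img = _four_constant_regions([0.1, 0.3, 0.6, 0.9])
    grid = partition_regions((8, 8), 4, overlap=0, patch_size=2)
    dist = compute_sampling_distribution(img, img, grid)
    np.testing.assert_array_equal(dist.Q, np.ones(4))
    np.testing.assert_array_equal(dist.P, np.full(4, 0.25))


def test_sampling_upweights_rare_region():
    """Three identical regions and one rare one: P = [1/6, 1/6, 1/6, 1/2]."""
    img = _four_constant_regions([0.1, 0.1, 0.1, 0.9])
    grid = partition_regions((8, 8), 4, overlap=0, patch_size=2)
    dist = compute_sampling_distribution(img, img, grid)
    np.testing.assert_allclose(dist.Q, [1 / 3, 1 / 3, 1 / 3, 1.0], rtol=0, atol=1e-15)
    np.testing.assert_allclose(dist.P, [1 / 6, 1 / 6, 1 / 6, 1 / 2], rtol=0, atol=1e-15)


def test_sampling_matches_brute_force_oracle():
    """Module Q/P equal an independent evaluation of the printed formulas."""
    rng = np.random.default_rng(42)
    worst = 0.0
    for _ in range(120):
        h = int(rng.integers(16, 64))
        w = int(rng.integers(16, 64))
        tol = int(rng.integers(8, min(h, w) + 1))
        source = rng.integers(0, 256, (h, w)).astype(np.float64) / 255.0
        target = rng.integers(0, 256, (h, w)).astype(np.float64) / 255.0
        grid = partition_regions((h, w), tol, overlap=0, patch_size=1)
        dist = compute_sampling_distribution(source, target, grid)
        q_ref, p_ref = brute_force_qp(source, target, grid)
        worst = max(worst, np.abs(dist.Q - q_ref).max(), np.abs(dist.P - p_ref).max())
    assert worst < 1e-12


def test_sampling_distribution_invariants(rng):
    source = rng.random((96, 96))
    target = rng.random((96, 96))
    grid = partition_regions((96, 96), 32, overlap=0, patch_size=16)
    dist = compute_sampling_distribution(source, target, grid)
    np.testing.assert_allclose(dist.H.sum(axis=1), 1.0, atol=1e-9)
    assert (dist.H >= 0).all()
    assert (dist.Q >= 0).all()
    assert abs(dist.P.sum() - 1.0) < 1e-9
    assert (dist.P >= 0).all()


def test_sampling_shape_mismatch_rejected(rng):
    grid = partition_regions((64, 64), 32, overlap=0, patch_size=16)
    with pytest.raises(ContractError):
        compute_sampling_distribution(rng.random((32, 32)), rng.random((64, 64)), grid)


def test_patch_sampling_one_hot_region(rng, aligned_dataset, four_region_grid):
    from uframe.regions import SamplingDistribution

    dist = SamplingDistribution(
        H=np.full((4, 64), 1 / 64), Q=np.array([0, 0, 1, 0.0]), P=np.array([0, 0, 1, 0.0])
    )
    for _ in range(20):
        _, _, k = sample_patch_pair(
            aligned_dataset.source, aligned_dataset.target, four_region_grid, dist, 64, rng
        )
        assert k == 2


def test_patch_sampling_frequencies_match_p(aligned_dataset, four_region_grid):
    rng = np.random.default_rng(123)
    dist = compute_sampling_distribution(
        aligned_dataset.source, aligned_dataset.target, four_region_grid
    )
    n = 10_000
    counts = np.zeros(4)
    for _ in range(n):
        sp, tp, k = sample_patch_pair(
            aligned_dataset.source, aligned_dataset.target, four_region_grid, dist, 64, rng
        )
        counts[k] += 1
        assert sp.shape == (64, 64) and tp.shape == (64, 64)
    sigma = np.sqrt(n * dist.P * (1 - dist.P))
    assert (np.abs(counts - n * dist.P) <= 3 * sigma).all()


def test_patch_sampling_deterministic(aligned_dataset, four_region_grid):
    dist = compute_sampling_distribution(
        aligned_dataset.source, aligned_dataset.target, four_region_grid
    )
    def draw(seed):
        rng = np.random.default_rng(seed)
        return [
            sample_patch_pair(
                aligned_dataset.source, aligned_dataset.target, four_region_grid, dist, 64, rng
            )
            for _ in range(10)
        ]
    a, b = draw(5), draw(5)
    for (sa, ta, ka), (sb, tb, kb) in zip(a, b):
        assert ka == kb
        np.testing.assert_array_equal(sa, sb)
        np.testing.assert_array_equal(ta, tb)
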