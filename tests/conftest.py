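import numpy as np
import pytest

from uframe.data import ImagePair
from uframe.networks import WidthConfig, build_networks
from uframe.regions import partition_regions
from uframe.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_width():
    return WidthConfig.tiny()


@pytest.fixture
def tiny_bundle(tiny_width):
    """Fresh 4-region bundle, single-channel both domains."""
    return build_networks(1, 1, 4, tiny_width, seed=0)


@pytest.fixture(scope="session")
def aligned_dataset():
    """Small pixel-aligned synthetic pair (identity misalignment path)."""
    spec = SyntheticSpec(
        image_size=256,
        cell_size=64,
        appearance="invert-gamma",
        misalign_mode="displace",
        misalign_d=0,
        jitter_shift=0,
        jitter_rotation=0,
        jitter_scale=0,
        noise_sigma=0.0,
        seed=7,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def aligned_pair(aligned_dataset):
    return ImagePair(aligned_dataset.source, aligned_dataset.target)


@pytest.fixture(scope="session")
def four_region_grid():
    return partition_regions((256, 256), 128, overlap=64, patch_size=64)
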