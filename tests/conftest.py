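import numpy as np
import pytest

from labnorm import BinaryMask, Volume, make_atlas, make_tie_mask


@pytest.fixture(scope="session")
def atlas_pair():
    """Noise-free identity-pose phantom playing the fixed-atlas role."""
    return make_atlas()


@pytest.fixture(scope="session")
def atlas(atlas_pair):
    return atlas_pair[0]


@pytest.fixture(scope="session")
def atlas_truth(atlas_pair):
    return atlas_pair[1]


@pytest.fixture(scope="session")
def tie_mask(atlas):
    # 5 voxels at 0.5 mm = 2.5 mm dilation, the working-resolution mask width
    return make_tie_mask(atlas, "otsu", 5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    return Volume(rng.normal(50, 10, (8, 8, 8)), (0.5, 0.5, 0.5), origin=(1.0, -2.0, 3.0))


def full_roi(vol: Volume) -> BinaryMask:
    return BinaryMask(np.ones(vol.shape, bool), vol.spacing, vol.origin, vol.direction)
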