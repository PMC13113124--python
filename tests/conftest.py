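import numpy as np
import pytest

from mitoquant import BinaryMask, ImageStack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_stack(rng):
    """A 2-channel 3-plane stack with random intensities and 0.1 µm voxels."""
    voxels = rng.random((2, 3, 32, 32)) * 100.0
    return ImageStack(voxels, (0.1, 0.1, 0.1), ["mito", "lc3"])


def random_mask_pair(rng, shape=(10, 12, 14), p=0.4, voxel_size=(1.0, 0.1, 0.1)):
    a = BinaryMask(rng.random(shape) < p, voxel_size)
    b = BinaryMask(rng.random(shape) < p, voxel_size)
    return a, b
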