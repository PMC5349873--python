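import numpy as np
import pytest

from cystrad.synthetic import BinormalMarkerSpec, generate_feature_table
from cystrad.texture import ImageVolume, ROIMask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_band_image():
    """2x2x1 volume [[0,0],[1,1]] with a full mask."""
    voxels = np.array([[0.0, 0.0], [1.0, 1.0]]).reshape(2, 2, 1)
    return ImageVolume(voxels), ROIMask(np.ones((2, 2, 1), bool))


@pytest.fixture
def checkerboard_image():
    voxels = np.array([[0.0, 1.0], [1.0, 0.0]]).reshape(2, 2, 1)
    return ImageVolume(voxels), ROIMask(np.ones((2, 2, 1), bool))


@pytest.fixture
def small_informative_table():
    """34/19 table with one strong marker, one moderate, a few noise."""
    specs = [BinormalMarkerSpec("strong", 0.9), BinormalMarkerSpec("moderate", 0.75)]
    return generate_feature_table(34, 19, specs, n_noise_markers=8, seed=77)


@pytest.fixture
def null_table():
    """All-noise 34/19 table."""
    return generate_feature_table(
        34, 19, [BinormalMarkerSpec("m1", 0.5)], n_noise_markers=29, seed=99
    )
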