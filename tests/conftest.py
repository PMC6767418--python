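import numpy as np
import pytest

from nirsvwm import forward_model as fm


@pytest.fixture(scope="session")
def small_grid():
    return fm.VoxelGrid(dims=(20, 20, 10), spacing=(2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def probe(small_grid):
    return fm.default_frontal_probe(small_grid)


@pytest.fixture(scope="session")
def profiles(small_grid, probe):
    return fm.synth_sensitivity(probe, small_grid)


@pytest.fixture(scope="session")
def full_mask(small_grid):
    return fm.MaskVolume(np.ones(small_grid.dims, bool), small_grid)
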