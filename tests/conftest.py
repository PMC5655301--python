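import numpy as np
import pytest

from rehofc.core import BrainMask, ImageGrid, Volume4D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid8():
    """8x8x8 grid, 3 mm isotropic, origin at (-12, -12, -12)."""
    return ImageGrid.isotropic((8, 8, 8), 3.0, origin_mm=(-12.0, -12.0, -12.0))


@pytest.fixture
def full_mask8(grid8):
    return BrainMask(grid=grid8, data=np.ones(grid8.dims, dtype=bool))


@pytest.fixture
def noise_vol8(grid8, rng):
    """Random 4D volume, 40 timepoints at TR 3 s."""
    return Volume4D(grid=grid8, data=rng.standard_normal(grid8.dims + (40,)), tr_seconds=3.0)


def make_volume(grid, data, tr=3.0):
    return Volume4D(grid=grid, data=data, tr_seconds=tr)
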