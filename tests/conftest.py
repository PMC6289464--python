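import numpy as np
import pytest
from hypothesis import settings

from entropymap.grey import NetMap
from entropymap.morphometry import RegionMask

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_region():
    """A 16x16 all-cell region mask."""
    return RegionMask(cell=np.ones((16, 16), dtype=bool))


def make_net(values, **kwargs):
    return NetMap(values=np.asarray(values, dtype=float), **kwargs)


@pytest.fixture
def make_netmap():
    return make_net
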