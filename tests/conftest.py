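import numpy as np
import pytest
from hypothesis import settings

from mfi.grid import make_grid

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def grid1d():
    return make_grid((-2.0, 2.0), 101)


@pytest.fixture
def grid1d_periodic():
    return make_grid((-np.pi, np.pi), 64, periodic=True)


@pytest.fixture
def grid2d():
    return make_grid([(-3.0, 3.0), (-3.0, 3.0)], 32)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
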