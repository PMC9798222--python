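import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cortecs as c

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocol112():
    """The six-shell, 112-encoding acquisition scheme."""
    return c.build_protocol(seed=0)


@pytest.fixture(scope="session")
def small_scheme():
    """A quick 16-encoding two-shell scheme for cheap tests."""
    return c.build_protocol([(1000, 6), (3000, 10)], seed=0)


@pytest.fixture(scope="session")
def grid2d_12():
    return c.SpectralGrid.logspaced(2, 12)


@pytest.fixture(scope="session")
def gt2d(grid2d_12):
    """Three-peak 2D ground-truth mixture on the default 12x12 grid."""
    return c.mixture_2d_default(grid2d_12)


@pytest.fixture(scope="session")
def radial_x():
    return np.array([1.0, 0.0, 0.0])
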