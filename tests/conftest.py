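import numpy as np
import pytest

from nsfdtumor import (
    interior_fixed_points,
    ns_critical_h,
    preset_kuznetsov,
)


@pytest.fixture(scope="session")
def discrete_params():
    """Preset used for the discrete-map experiments (rho = 1.131)."""
    return preset_kuznetsov("discrete")


@pytest.fixture(scope="session")
def continuous_params():
    """Preset used for the ODE runs (rho = 11.131)."""
    return preset_kuznetsov("continuous")


@pytest.fixture(scope="session")
def interior_fp(discrete_params):
    """Smallest-y interior fixed point of the discrete preset."""
    fps = interior_fixed_points(discrete_params)
    assert fps, "discrete preset must have an interior fixed point"
    return fps[0]


@pytest.fixture(scope="session")
def ns_partial(discrete_params):
    """Neimark-Sacker critical-step report for the discrete preset."""
    rep = ns_critical_h(discrete_params)
    assert rep.h_crit is not None
    return rep


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220707)
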