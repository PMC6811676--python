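import numpy as np
import pytest
from scipy.integrate import solve_ivp

from metallonmr import ExchangeSystem, NoePairSystem


@pytest.fixture
def delays():
    return np.geomspace(0.01, 0.5, 16)


@pytest.fixture
def zz_system():
    """The z-z exchange study conditions: k1 = 3.5, k_rev = 7.7, R1 = 2 s^-1."""
    return ExchangeSystem(3.5, 7.7, 2.0)


@pytest.fixture
def noesy_system():
    """The NOESY study conditions: k1 = 4.3, k_rev = 8.8, sigma = -1 s^-1."""
    return NoePairSystem(ExchangeSystem(4.3, 8.8, 2.0), -1.0, -1.0)


def ode_propagate(K, m0, times):
    """Independent oracle: adaptive ODE integration of dM/dt = K M."""
    K = np.asarray(K, float)
    times = np.asarray(times, float)
    t_span = (0.0, float(times.max()) if times.size else 1.0)
    sol = solve_ivp(
        lambda t, m: K @ m,
        t_span,
        np.asarray(m0, float),
        t_eval=times,
        rtol=1e-11,
        atol=1e-13,
        method="DOP853",
    )
    assert sol.success
    return sol.y.T
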