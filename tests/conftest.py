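import numpy as np
import pytest

from cainfer import KineticParams, KineticState


@pytest.fixture(scope="session")
def table_params() -> KineticParams:
    """Literature parameter values."""
    return KineticParams()


@pytest.fixture(scope="session")
def prior_state() -> KineticState:
    """Prior-mean initial state of the inversion."""
    return KineticState(0.1, 0.5, 0.5)


def rk4_reference(state0, params, duration, h=1e-3):
    """Classical 4th-order Runge-Kutta at a fine step: the integration
    oracle for the microtime Euler scheme."""
    from cainfer.kinetic_model import _derivative

    def rhs(x):
        dc, dq, dp = _derivative(x[0], x[1], x[2], params)
        return np.array([dc, dq, dp])

    x = state0.as_array()
    n = int(round(duration / h))
    for _ in range(n):
        k1 = rhs(x)
        k2 = rhs(x + 0.5 * h * k1)
        k3 = rhs(x + 0.5 * h * k2)
        k4 = rhs(x + h * k3)
        x = x + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return x
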