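import numpy as np
import pytest

from qclamp import (
    CONTROL_PARAMETERS,
    apply_ml277,
    make_standard_protocol,
)


@pytest.fixture(scope="session")
def control():
    return CONTROL_PARAMETERS


@pytest.fixture(scope="session")
def ml277(control):
    return apply_ml277(control)


@pytest.fixture(scope="session")
def iv_family():
    return make_standard_protocol("iv_family")


@pytest.fixture(scope="session")
def step_protocol():
    return make_standard_protocol("single_step_40mV_4s")


def rk4_step_matrix(q, h):
    """One classical RK4 step of the linear master equation dp/dt = p Q.

    For a linear right-hand side the RK4 update is exactly
    p_{n+1} = p_n @ (I + hQ + (hQ)^2/2 + (hQ)^3/6 + (hQ)^4/24),
    the degree-4 Taylor polynomial of the propagator, so the whole fixed-step
    integration reduces to repeated multiplication by this matrix.
    """
    hq = h * q
    m = np.eye(q.shape[0])
    term = np.eye(q.shape[0])
    for k in range(1, 5):
        term = term @ hq / k
        m = m + term
    return m


def rk4_occupancy(q_of_v, protocol, init, dt=0.001):
    """Independent fixed-step 4th-order integrator of dp/dt = p Q(v(t)).

    Oracle for the matrix-exponential propagation: classical RK4 at step
    ``dt`` ms within each epoch, sampled on the protocol's output grid.
    The default 1 us step keeps RK4 inside its stability region for the
    stiffest printed rate (k2 ~ 853 ms^-1).
    """
    p = np.asarray(init, dtype=float).copy()
    out = [p.copy()]
    t_grid = protocol.time_grid()
    k = 1
    t_cur = 0.0
    for epoch in protocol.epochs:
        q = q_of_v(epoch.v)

        def advance(x, span):
            n_steps = max(int(round(span / dt)), 1)
            h = span / n_steps
            return x @ np.linalg.matrix_power(rk4_step_matrix(q, h), n_steps)

        t_end = t_cur + epoch.duration
        while k < t_grid.size and t_grid[k] <= t_end + 1e-9:
            p = advance(p, t_grid[k] - t_cur)
            t_cur = t_grid[k]
            out.append(p.copy())
            k += 1
        if t_cur < t_end - 1e-9:
            p = advance(p, t_end - t_cur)  # boundary off the grid
            t_cur = t_end
    return np.array(out)
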