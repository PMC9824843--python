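import numpy as np
import pytest

from lignivis.kinetics import InitialConditions, KineticParams


def euler_oracle(
    params: KineticParams,
    init: InitialConditions,
    t_end: float = 5.0,
    dt: float = 1e-4,
):
    """Fixed-step forward-Euler integration of the methylolation system.

    Deliberately independent of the package's closed-form/adaptive solver:
    steps dF = (-k1*P*F - k2*F^2) dt, dP = -k1*P*F dt on the reactive pool.
    Returns (times, F, P_reactive) at every step boundary.
    """
    n = int(round(t_end / dt))
    F = np.empty(n + 1)
    P = np.empty(n + 1)
    F[0] = init.F0
    P[0] = init.POH0 * (1.0 - params.f_nonreactive)
    f, p = F[0], P[0]
    k1, k2 = params.k1, params.k2
    for i in range(1, n + 1):
        main = k1 * p * f
        f += (-main - k2 * f * f) * dt
        p += -main * dt
        F[i] = f
        P[i] = p
    return np.linspace(0.0, t_end, n + 1), F, P


@pytest.fixture(scope="session")
def sls_conditions():
    from lignivis.presets import SLS_60

    return SLS_60


@pytest.fixture(scope="session")
def hls50_conditions():
    from lignivis.presets import HLS_50

    return HLS_50
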