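"""Independent numerical oracles used by the tests.

These deliberately avoid the closed forms implemented in the package: the
step-out average is obtained by integrating the overdamped driven-rotor
equation of motion directly.
"""

import numpy as np
from scipy.integrate import solve_ivp


def rotor_average_rate(f: float, f_c: float, min_time: float = 10.0) -> float:
    """Time-averaged rotation rate (Hz) of dphi/dt = omega_c sin(omega t - phi).

    Above step-out the slip phase chi = omega*t - phi is autonomous with
    period 1/sqrt(f^2 - f_c^2); integrating over an integer number of slip
    periods makes the average exact.  Below step-out the rotor phase-locks
    and a long window bounds the transient contribution.
    """
    omega = 2 * np.pi * f
    omega_c = 2 * np.pi * f_c
    if f == 0:
        return 0.0
    if f > f_c:
        beat = np.sqrt(f**2 - f_c**2)
        n_periods = max(int(np.ceil(min_time * beat)), 5)
        total_t = n_periods / beat
    else:
        total_t = max(min_time, 100.0 / f)

    def rhs(t, y):
        return [omega_c * np.sin(omega * t - y[0])]

    sol = solve_ivp(
        rhs,
        (0.0, total_t),
        [0.0],
        rtol=1e-10,
        atol=1e-10,
        max_step=0.05 / max(f, f_c, 1.0),
        dense_output=False,
    )
    return float(sol.y[0, -1] / (2 * np.pi * total_t))
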