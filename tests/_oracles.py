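"""Independent brute-force oracles for the diffusion primitives.

The Euler–Maruyama simulator integrates the accumulation process directly at a
small step size, sharing no code with the series-based density or the
inverse-CDF sampler it is used to check.  Discrete-time simulation misses
within-step boundary excursions, which biases first-passage times upward by
O(sqrt(dt)); the standard Broadie–Glasserman–Kou continuity correction
(boundaries pulled inward by 0.5826*sigma*sqrt(dt)) removes the leading-order
bias.  Test-only; never part of the pipeline.
"""

import numpy as np
from numba import njit

EULER_DT = 1e-4
_BGK = 0.5826  # -zeta(1/2)/sqrt(2*pi), the continuity-correction constant


@njit(cache=True)
def euler_trials(v, a, z, t0, n, seed, dt=EULER_DT, t_cap=30.0):
    """Simulate n first passages by Euler integration with the BGK correction.

    Returns (choices, rts); choice 1 = upper boundary.  Trials that fail to
    absorb before t_cap are assigned the nearer boundary at t_cap (mass is
    negligible for the parameter ranges used in tests).
    """
    np.random.seed(seed)
    sdt = np.sqrt(dt)
    shift = _BGK * sdt  # effective boundary pulled inward per BGK
    lo = shift
    hi = a - shift
    choices = np.empty(n, dtype=np.int64)
    rts = np.empty(n)
    for i in range(n):
        x = z * a
        t = 0.0
        while lo < x < hi and t < t_cap:
            x += v * dt + sdt * np.random.normal()
            t += dt
        choices[i] = 1 if x >= a * 0.5 else 0
        rts[i] = t0 + t
    return choices, rts
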