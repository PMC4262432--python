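"""Two-variable excitable reference model for solver verification.

A cubic-excitation / linear-recovery system in FitzHugh-Nagumo form,

    dv/dt = K v (v - A)(1 - v) - w + I_stim
    dw/dt = EPS (G v - w)

with v dimensionless in ~[0, 1]. Coefficients::

    K = 4.0, A = 0.1, EPS = 0.01, G = 0.5

It is deliberately simple (closed-form right-hand side, two states) so FEM
and operator-splitting machinery can be verified independently of the stiff
ionic model. Not a physiological cell model.
"""

from __future__ import annotations

import numpy as np
from numba import njit

K = 4.0
A = 0.1
EPS = 0.01
G = 0.5

N_STATES = 1  # internal states (w); v kept separately
REST_V = 0.0
REST_Q = np.zeros(1)


DEFAULT_PV = np.array([K, A, EPS, G])


def rhs(v: float, w: float, istim: float = 0.0, pv=None):
    """Right-hand side (dv/dt, dw/dt); iion = -(cubic) so dv = -(iion-istim)."""
    k, a, eps, g = DEFAULT_PV if pv is None else pv
    dv = k * v * (v - a) * (1.0 - v) - w + istim
    dw = eps * (g * v - w)
    return dv, dw


@njit(cache=True)
def step_states(V, Q, dt, mult, pv, iion):
    """Kernel-compatible state step: advances w, reports iion = -(f(v) - w).

    ``pv`` packs the coefficients (K, A, EPS, G)."""
    k, a, eps, g = pv[0], pv[1], pv[2], pv[3]
    n = V.shape[0]
    for i in range(n):
        v = V[i]
        w = Q[i, 0]
        iion[i] = -(k * v * (v - a) * (1.0 - v) - w)
        Q[i, 0] = w + dt * eps * (g * v - w)
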