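"""Array-oriented stepping kernels shared by single-cell and tissue solvers.

A population of cells is held as ``V`` (n,) and ``Q`` (n, 25) arrays plus a
(n, 6) array of regional multipliers ``[gto, gks, gna, gca, gk1, bias]``. The same
compiled kernel advances an isolated myocyte (n=1), all myocardial nodes of a
3D mesh, and the Purkinje surrogate nodes of a coupled system.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .mahajan import (N_GATES, N_STATES, YF_SLOPE, YF_TAU, YF_VHALF,
                      CellParameters, _eval_cell)

#: column order of the multiplier array
MULT_COLS = ("gto", "gks", "gna", "gca", "gk1", "bias")
VENTRICULAR_MULT = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 0.0])

#: conduction-system (Purkinje) surrogate: the ventricular model
#: re-parameterized for a fast upstroke (g_Na x2), a prominent early rapid
#: repolarization notch (I_to x1.7), a slightly negative plateau, a longer
#: action potential (I_Ks x0.08), and slow diastolic depolarization between
#: beats (I_K1 x0.25 plus a 1 uA/uF inward pacemaker current through the
#: slow gate yf). At 400 ms pacing: APD90 ~267 ms, max dV/dt ~407 mV/ms,
#: mid-plateau mean ~-3 mV, diastolic rise ~+2 mV per cycle (no spontaneous
#: firing at cycle lengths up to 1 s).
PURKINJE_MULT = np.array([1.7, 0.08, 2.0, 1.0, 0.25, -1.0])


def params_vector(p: CellParameters) -> np.ndarray:
    """Pack CellParameters into the flat float64 layout the kernel expects."""
    return np.array([
        p.frt, p.na_o, p.k_i, p.k_o, p.ca_o,
        p.g_ca, p.g_tos, p.g_tof, p.g_ks, p.g_naca, p.g_kr, p.g_k1, p.g_nak,
        p.v_up, p.tau_sd, p.g_na, p.tau_r, p.tau_a,
        p.release_slope, p.c_star,
    ])


@njit(cache=True)
def _eval_mult(v, q, pv, gto, gks, gna, gca, gk1, bias, xinf, tau, dq):
    iion = _eval_cell(
        v, q, pv[0], pv[1], pv[2], pv[3], pv[4],
        pv[5] * gca, pv[6] * gto, pv[7] * gto, pv[8] * gks, pv[9],
        pv[10], pv[11] * gk1, pv[12], pv[13], pv[14], pv[15] * gna,
        pv[16], pv[17], pv[18], pv[19],
        xinf, tau, dq)
    # pacemaker current: amplitude ``bias`` (uA/uF, negative = inward) carried
    # by the slow hyperpolarization-activated gate yf (last state). The gate
    # opens during diastole and shuts during the action potential, so a
    # nonzero bias produces slow diastolic depolarization between beats.
    yinf = 1.0 / (1.0 + np.exp((v - YF_VHALF) / YF_SLOPE))
    dq[N_STATES - 1] = (yinf - q[N_STATES - 1]) / YF_TAU
    return iion + bias * q[N_STATES - 1]


@njit(cache=True)
def step_states(V, Q, dt, mult, pv, iion):
    """Advance internal states of every cell by ``dt`` at frozen voltage.

    Rush-Larsen exponential updates for the ten HH gates, forward Euler for
    the Markov chain, calcium subsystem and [Na]. ``iion`` receives the total
    ionic current density (uA/uF, outward positive) evaluated at entry state;
    the caller owns the voltage update (point cell or FEM ionic-current
    interpolation).
    """
    n = V.shape[0]
    xinf = np.empty(N_STATES)
    tau = np.empty(N_STATES)
    dq = np.empty(N_STATES)
    for i in range(n):
        q = Q[i]
        iion[i] = _eval_mult(V[i], q, pv, mult[i, 0], mult[i, 1], mult[i, 2],
                             mult[i, 3], mult[i, 4], mult[i, 5], xinf, tau, dq)
        for g in range(N_GATES):
            q[g] = xinf[g] + (q[g] - xinf[g]) * np.exp(-dt / tau[g])
        for s in range(N_GATES, N_STATES):
            q[s] = q[s] + dt * dq[s]


@njit(cache=True)
def rates(V, Q, mult, pv, dV, dQ, iion, istim):
    """Time derivatives of every cell (for references/oracles, no stepping)."""
    n = V.shape[0]
    xinf = np.empty(N_STATES)
    tau = np.empty(N_STATES)
    for i in range(n):
        iion[i] = _eval_mult(V[i], Q[i], pv, mult[i, 0], mult[i, 1],
                             mult[i, 2], mult[i, 3], mult[i, 4], mult[i, 5],
                             xinf, tau, dQ[i])
        dV[i] = -(iion[i] - istim[i])
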