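"""Single-cell protocols: rate evaluation, pacing, APD and restitution.

All stimuli follow the convention that a positive amplitude (uA/uF)
depolarizes the cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .kernel import params_vector, step_states
from .mahajan import N_STATES, CellParameters, CellState, rest_state


class DivergenceError(RuntimeError):
    """Raised when the membrane voltage leaves the physical range."""


class NoBeatError(ValueError):
    """Raised when a trace contains no action potential."""


@dataclass(frozen=True)
class StimulusSpec:
    """Periodic current-pulse pacing protocol.

    amplitude in uA/uF (depolarizing positive), onset/duration/cycle length
    in ms.
    """

    amplitude: float = 40.0
    onset: float = 0.0
    duration: float = 1.0
    cycle_length: float = 400.0
    n_beats: int = 1

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("stimulus duration must be > 0")
        if not self.cycle_length > self.duration:
            raise ValueError("cycle length must exceed stimulus duration")


def evaluate_rates(state: CellState, params: CellParameters | None = None,
                   stim: float = 0.0,
                   mult: np.ndarray | None = None):
    """Time derivatives (dV/dt, dq/dt) and total ionic current of one cell.

    ``mult`` is the optional regional multiplier vector
    [gto, gks, gna, gca, gk1, bias]; ``stim`` a current density in uA/uF.
    Satisfies dV/dt = -(I_ion - I_stim) with membrane capacitance folded
    into the current units.
    """
    from .kernel import VENTRICULAR_MULT, rates

    params = params or CellParameters()
    if not np.isfinite(state.v) or not np.all(np.isfinite(state.q)):
        raise ValueError("non-finite entries in cell state")
    m = (VENTRICULAR_MULT if mult is None else np.asarray(mult, float))[None, :]
    V = np.array([state.v])
    Q = state.q[None, :].copy()
    dV = np.zeros(1)
    dQ = np.zeros((1, N_STATES))
    iion = np.zeros(1)
    rates(V, Q, m, params_vector(params), dV, dQ, iion, np.array([stim]))
    return dV[0], dQ[0], iion[0]


@njit(cache=True)
def _run_paced(V, Q, mult, pv, dt, amp, onset, dur, cl, n_beats,
               stride, v_out, t_out, ci_out):
    """Pace ``n_beats`` cycles; record V of the final beat every ``stride`` steps."""
    iion = np.empty(1)
    nstep = int(round(cl / dt))
    m = 0
    for b in range(n_beats):
        last = b == n_beats - 1
        for k in range(nstep):
            t = k * dt
            if last and k % stride == 0:
                t_out[m] = t
                v_out[m] = V[0]
                ci_out[m] = Q[0, 18]
                m += 1
            step_states(V, Q, dt, mult, pv, iion)
            stim = amp if (onset <= t < onset + dur) else 0.0
            V[0] += dt * (-iion[0] + stim)
            if np.abs(V[0]) > 1000.0:
                return -1
    return m


def integrate_cell(initial: CellState | None, protocol: StimulusSpec,
                   dt: float = 0.05, params: CellParameters | None = None,
                   mult: np.ndarray | None = None, output_every: float = 0.1):
    """Pace an isolated cell and return (time, voltage, [Ca]_i) of the last
    beat plus the final state for restart.

    Time axis is relative to the final beat's cycle start. Raises
    DivergenceError if |V| exceeds 1000 mV.
    """
    from .kernel import VENTRICULAR_MULT

    params = params or CellParameters()
    state = (initial or rest_state()).copy()
    if dt <= 0:
        raise ValueError("dt must be positive")
    m = (VENTRICULAR_MULT if mult is None else np.asarray(mult, float))[None, :].copy()
    V = np.array([state.v])
    Q = state.q[None, :].copy()
    stride = max(1, int(round(output_every / dt)))
    nrec = int(round(protocol.cycle_length / dt)) // stride + 1
    t_out = np.zeros(nrec)
    v_out = np.zeros(nrec)
    ci_out = np.zeros(nrec)
    n = _run_paced(V, Q, m, params_vector(params), dt, protocol.amplitude,
                   protocol.onset, protocol.duration, protocol.cycle_length,
                   protocol.n_beats, stride, v_out, t_out, ci_out)
    if n < 0:
        raise DivergenceError(
            f"voltage diverged (|V| > 1000 mV) at dt={dt} ms; reduce the step")
    final = CellState(V[0], Q[0].copy())
    return t_out[:n], v_out[:n], ci_out[:n], final


def measure_apd(t: np.ndarray, v: np.ndarray, repol_fraction: float = 0.9):
    """APD and diastolic intervals of a voltage trace.

    The threshold level is ``vmax - repol_fraction*(vmax - vmin)``; each
    action potential is the interval between an upward and the following
    downward crossing of that level, both linearly interpolated between
    samples. Returns (apds, dis): durations of complete APs and the
    diastolic intervals separating them.
    """
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("time and voltage arrays must be equal-length 1D")
    vmax, vmin = v.max(), v.min()
    if vmax - vmin < 5.0:
        raise NoBeatError("no action potential found in trace (flat)")
    level = vmax - repol_fraction * (vmax - vmin)
    above = v > level
    ups, downs = [], []
    for i in range(len(v) - 1):
        if not above[i] and above[i + 1]:
            f = (level - v[i]) / (v[i + 1] - v[i])
            ups.append(t[i] + f * (t[i + 1] - t[i]))
        elif above[i] and not above[i + 1]:
            f = (level - v[i]) / (v[i + 1] - v[i])
            downs.append(t[i] + f * (t[i + 1] - t[i]))
    if above[0]:  # already depolarized at the first sample
        ups.insert(0, t[0])
    if not ups or not downs:
        raise NoBeatError("no complete action potential found in trace")
    apds, dis = [], []
    d = 0
    prev_down = None
    for u in ups:
        while d < len(downs) and downs[d] <= u:
            d += 1
        if d == len(downs):
            break
        apds.append(downs[d] - u)
        if prev_down is not None:
            dis.append(u - prev_down)
        prev_down = downs[d]
    if not apds:
        raise NoBeatError("no complete action potential found in trace")
    return np.array(apds), np.array(dis)


def steady_state_apd(mult: np.ndarray | None = None,
                     params: CellParameters | None = None,
                     cycle_length: float = 400.0, n_beats: int = 20,
                     dt: float = 0.05, repol_fraction: float = 0.9) -> float:
    """APD at the steady-state beat of periodic pacing (ms)."""
    spec = StimulusSpec(cycle_length=cycle_length, n_beats=n_beats)
    t, v, _, _ = integrate_cell(None, spec, dt=dt, params=params, mult=mult)
    apds, _ = measure_apd(t, v, repol_fraction)
    return float(apds[0])


def restitution_curve(mult: np.ndarray | None = None,
                      cycle_lengths=(400.0, 350.0, 300.0, 250.0),
                      params: CellParameters | None = None,
                      n_beats: int = 20, dt: float = 0.05,
                      repol_fraction: float = 0.9):
    """(diastolic interval, APD) pairs across pacing rates.

    Cycle lengths must be sorted descending; pacing at each rate starts from
    the previous rate's final state (standard dynamic protocol). Cycle
    lengths that lose 1:1 capture are flagged and omitted.
    """
    cls = list(cycle_lengths)
    if any(b >= a for a, b in zip(cls, cls[1:])):
        raise ValueError("cycle lengths must be sorted descending")
    state = rest_state()
    out, skipped = [], []
    for cl in cls:
        spec = StimulusSpec(cycle_length=cl, n_beats=n_beats)
        t, v, _, state = integrate_cell(state, spec, dt=dt, params=params,
                                        mult=mult)
        try:
            apds, _ = measure_apd(t, v, repol_fraction)
        except NoBeatError:
            skipped.append(cl)
            continue
        if len(apds) != 1 or apds[0] > cl:  # 2:1 block or alternans wrap
            skipped.append(cl)
            continue
        di = cl - apds[0]
        out.append((float(di), float(apds[0])))
    return out, skipped
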