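"""Nine regional ventricular variants and their conductance calibration.

The ventricle is split into transmural zones (endo, M, epi) crossed with
apex-to-base zones (apex, center, base). Regional electrophysiology enters
through two conductance multipliers per region:

* ``gto_mult`` scales both transient-outward components and is fixed a
  priori by the transmural current-density rule: endocardial peak I_to is
  15% below epicardial, M cells share the epicardial value.
* ``gks_mult`` scales the slow delayed rectifier and is tuned by scalar
  root finding until the steady-state APD90 under 400 ms pacing matches the
  region's target.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .kernel import params_vector, step_states
from .mahajan import CellParameters, rest_state
from .single import steady_state_apd

TRANSMURAL_ZONES = ("endo", "M", "epi")
LONGITUDINAL_ZONES = ("apex", "center", "base")

#: target APD90 (ms) under steady 400 ms pacing, by (transmural, longitudinal)
TARGET_APD = {
    ("epi", "apex"): 168.0, ("epi", "center"): 177.0, ("epi", "base"): 186.0,
    ("M", "apex"): 195.0, ("M", "center"): 205.0, ("M", "base"): 216.0,
    ("endo", "apex"): 189.0, ("endo", "center"): 199.0, ("endo", "base"): 209.0,
}

#: transmural I_to scaling: endocardial peak I_to 15% below epicardial;
#: no apex-base variation of I_to is imposed
GTO_MULT = {"epi": 1.0, "M": 1.0, "endo": 0.85}


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class RegionalVariant:
    transmural_zone: str
    longitudinal_zone: str
    gto_mult: float
    gks_mult: float
    target_apd_ms: float
    achieved_apd_ms: float = np.nan

    def __post_init__(self) -> None:
        if self.transmural_zone not in TRANSMURAL_ZONES:
            raise ValueError(f"unknown transmural zone {self.transmural_zone}")
        if self.longitudinal_zone not in LONGITUDINAL_ZONES:
            raise ValueError(f"unknown longitudinal zone {self.longitudinal_zone}")
        if not (self.gto_mult > 0 and self.gks_mult > 0):
            raise ValueError("conductance multipliers must be positive")

    @property
    def mult(self) -> np.ndarray:
        """Kernel multiplier vector [gto, gks, gna, gca, gk1, bias]."""
        return np.array([self.gto_mult, self.gks_mult, 1.0, 1.0, 1.0, 0.0])

    @property
    def label(self) -> str:
        return f"{self.transmural_zone}/{self.longitudinal_zone}"


def calibrate_regional_variants(targets: dict | None = None,
                                params: CellParameters | None = None,
                                cycle_length: float = 400.0,
                                n_beats: int = 20, dt: float = 0.05,
                                tol_ms: float = 0.5,
                                bracket=(0.02, 50.0)) -> list[RegionalVariant]:
    """Calibrate all nine regional variants against their APD targets.

    Deterministic: Brent root finding on the gks multiplier (log scale)
    with a fixed bracket; raises CalibrationError naming the achievable APD
    range if a target falls outside it.
    """
    targets = dict(TARGET_APD if targets is None else targets)
    params = params or CellParameters()
    out = []
    for tz in TRANSMURAL_ZONES:
        gto = GTO_MULT[tz]
        cache: dict[float, float] = {}

        def apd_of(log_gks: float) -> float:
            if log_gks not in cache:
                m = np.array([gto, float(np.exp(log_gks)), 1.0, 1.0, 1.0, 0.0])
                cache[log_gks] = steady_state_apd(
                    m, params, cycle_length, n_beats, dt)
            return cache[log_gks]

        lo, hi = np.log(bracket[0]), np.log(bracket[1])
        for lz in LONGITUDINAL_ZONES:
            target = targets[(tz, lz)]
            f = lambda x: apd_of(x) - target
            f_lo, f_hi = f(lo), f(hi)
            if f_lo * f_hi > 0:
                raise CalibrationError(
                    f"target {target} ms for {tz}/{lz} outside achievable "
                    f"APD range [{apd_of(hi):.1f}, {apd_of(lo):.1f}] ms")
            x = brentq(f, lo, hi, xtol=1e-5)
            achieved = apd_of(x)
            if abs(achieved - target) > max(tol_ms, 1.0):
                raise CalibrationError(
                    f"{tz}/{lz}: achieved {achieved:.2f} ms vs target {target}")
            out.append(RegionalVariant(tz, lz, gto, float(np.exp(x)),
                                       target, achieved))
    return out


def variant_table(variants) -> "object":
    """Regional variant list as a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame([{
        "transmural_zone": v.transmural_zone,
        "longitudinal_zone": v.longitudinal_zone,
        "gto_mult": v.gto_mult,
        "gks_mult": v.gks_mult,
        "target_apd_ms": v.target_apd_ms,
        "achieved_apd_ms": v.achieved_apd_ms,
    } for v in variants])


def write_variants_csv(path, variants) -> None:
    variant_table(variants).to_csv(path, index=False)


def read_variants_csv(path) -> list[RegionalVariant]:
    import pandas as pd

    df = pd.read_csv(path)
    return [RegionalVariant(r.transmural_zone, r.longitudinal_zone,
                            float(r.gto_mult), float(r.gks_mult),
                            float(r.target_apd_ms), float(r.achieved_apd_ms))
            for r in df.itertuples()]


def transient_outward_current(v: float, q: np.ndarray, gto_mult: float = 1.0,
                              params: CellParameters | None = None) -> float:
    """I_to (slow + fast components, uA/uF) at a given voltage and state."""
    p = params or CellParameters()
    ek = np.log(p.k_o / p.k_i) / p.frt
    rt1 = -(v + 3.0) / 15.0
    rt2 = (v + 33.5) / 10.0
    rs_inf = 1.0 / (1.0 + np.exp(rt2))
    xtos, ytos, xtof, ytof = q[6], q[7], q[8], q[9]
    itos = p.g_tos * gto_mult * xtos * (ytos + 0.5 * rs_inf) * (v - ek)
    itof = p.g_tof * gto_mult * xtof * ytof * (v - ek)
    return float(itos + itof)


def peak_ito_under_clamp(gto_mult: float = 1.0,
                         params: CellParameters | None = None,
                         v_hold: float = -80.0, v_step: float = 20.0,
                         t_hold: float = 500.0, t_step: float = 300.0,
                         dt: float = 0.05) -> float:
    """Peak transient-outward current density under a square voltage clamp.

    Holds the membrane at ``v_hold``, steps to ``v_step``, and returns the
    maximum I_to during the step. Used to verify the transmural
    current-density rule.
    """
    p = params or CellParameters()
    pv = params_vector(p)
    st = rest_state()
    mult = np.array([[gto_mult, 1.0, 1.0, 1.0, 1.0, 0.0]])
    V = np.array([v_hold])
    Q = st.q[None, :].copy()
    iion = np.zeros(1)
    for _ in range(int(round(t_hold / dt))):
        step_states(V, Q, dt, mult, pv, iion)  # V frozen: clamp
    V[0] = v_step
    peak = 0.0
    for _ in range(int(round(t_step / dt))):
        step_states(V, Q, dt, mult, pv, iion)
        peak = max(peak, transient_outward_current(v_step, Q[0], gto_mult, p))
    return peak
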