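"""Rabbit ventricular myocyte model (Mahajan-type) with regional conductance scaling.

The model combines a Luo-Rudy-type fast sodium current, rapid and slow delayed
rectifiers (the slow component carrying a calcium-sensitive conductance), fast and
slow transient-outward potassium currents, an inward rectifier, Na/K pump,
allosterically regulated Na/Ca exchange, a seven-state Markov L-type calcium
channel gated by dyadic calcium, and a four-compartment calcium cycling subsystem
(dyadic junction, submembrane space, bulk myoplasm, sarcoplasmic reticulum) with
graded SR release. It was built for rabbit ventricle and retains steep APD
restitution at rapid pacing, which is what makes it usable for reentry studies.

State layout (24 internal variables, voltage kept separately):

====  =========  ==========================================================
idx   name       meaning
====  =========  ==========================================================
0-2   xm,xh,xj   INa activation / fast / slow inactivation gates
3     xr         IKr activation gate
4-5   xs1,xs2    IKs activation gates (xs2 four-fold slower)
6-7   xtos,ytos  slow Ito activation / inactivation
8-9   xtof,ytof  fast Ito activation / inactivation
10-15 c1,c2,     Markov L-type Ca channel occupancies; open probability is
      xi1ca,     po = 1 - (sum of the six closed/inactivated states)
      xi1ba,
      xi2ca,
      xi2ba
16    cp         dyadic junction [Ca] (uM)
17    cs         submembrane [Ca] (uM)
18    ci         bulk myoplasmic [Ca] (uM)
19    cj         SR load (uM)
20    cjp        time-averaged SR load driving release (uM)
21    xir        SR release flux (uM/ms)
22    nai        intracellular [Na] (mM)
23    tropi      Ca bound to troponin, myoplasm (uM)
24    trops      Ca bound to troponin, submembrane (uM)
====  =========  ==========================================================

Gates 0-9 are Hodgkin-Huxley and are advanced with Rush-Larsen updates; the
Markov chain, calcium subsystem and [Na] are advanced with forward Euler.

Per-node regional scaling enters through five multipliers
(gto, gks, gna, gca, plus an additive background/pacemaker current `bias`
in uA/uF, negative = depolarizing) so a single compiled kernel serves
ventricular regional variants and the Purkinje surrogate alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
from numba import njit

N_STATES = 26  # internal states, V excluded

STATE_NAMES = (
    "xm", "xh", "xj", "xr", "xs1", "xs2", "xtos", "ytos", "xtof", "ytof",
    "c1", "c2", "xi1ca", "xi1ba", "xi2ca", "xi2ba",
    "cp", "cs", "ci", "cj", "cjp", "xir", "nai", "tropi", "trops",
    "yf",
)
N_GATES = 10  # leading Hodgkin-Huxley gates (Rush-Larsen updated)

#: slow hyperpolarization-activated pacemaker gate ``yf`` (last state):
#: carries current only when the regional "bias" multiplier is nonzero
#: (the conduction-system surrogate); in ventricular cells it evolves
#: silently. First-order kinetics toward a sigmoid open below ~ -72 mV.
YF_VHALF = -72.0   # mV, half-activation
YF_SLOPE = 6.0     # mV, activation slope
YF_TAU = 150.0     # ms, activation/deactivation time constant


@dataclass(frozen=True)
class CellParameters:
    """Fixed parameters of the ventricular model.

    Defaults are the published simulation values; conductances in mS/uF,
    concentrations in mM, temperature in K.
    """

    na_o: float = 136.0          # external [Na], mM
    k_i: float = 140.0           # internal [K], mM
    k_o: float = 5.4             # external [K], mM
    ca_o: float = 1.8            # external [Ca], mM
    g_ca: float = 182.0          # Ca-flux strength, mmol/(cm C)
    g_tos: float = 0.04          # slow transient-outward conductance
    g_tof: float = 0.11          # fast transient-outward conductance
    g_ks: float = 0.1386         # slow delayed-rectifier conductance
    g_naca: float = 0.84         # Na/Ca exchanger strength, uM/ms
    g_kr: float = 0.0125         # rapid delayed-rectifier conductance
    g_k1: float = 0.3            # inward-rectifier conductance
    g_nak: float = 1.5           # Na/K pump strength
    v_up: float = 0.4            # SR uptake strength, uM/ms
    tau_sd: float = 4.0          # submembrane-myoplasm diffusion time, ms
    g_na: float = 12.0           # fast sodium conductance
    tau_r: float = 30.0          # spark lifetime, ms
    tau_a: float = 100.0         # SR relaxation time, ms
    release_slope: float = 11.3  # graded-release slope (dimensionless gain)
    c_star: float = 90.0         # steep-release threshold, uM
    temperature: float = 308.0   # K
    gas_const: float = 8.314     # J / (mol K)
    faraday: float = 96.485      # C / mmol

    def __post_init__(self) -> None:
        conc = ("na_o", "k_i", "k_o", "ca_o")
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in conc and not v > 0:
                raise ValueError(f"concentration {f.name} must be > 0, got {v}")
            if f.name.startswith("g_") and v < 0:
                raise ValueError(f"conductance {f.name} must be >= 0, got {v}")

    @property
    def frt(self) -> float:
        """F/(R T) in 1/mV (F in C/mmol, R in J/(mol K))."""
        return self.faraday / (self.gas_const * self.temperature)


@dataclass
class CellState:
    """Voltage plus ordered internal state vector of one cell."""

    v: float
    q: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (N_STATES,):
            raise ValueError(f"state vector must have {N_STATES} entries")
        if not np.isfinite(self.v) or not np.all(np.isfinite(self.q)):
            raise ValueError("non-finite entries in cell state")
        gates = self.q[:N_GATES]
        if np.any(gates < -1e-9) or np.any(gates > 1 + 1e-9):
            raise ValueError("gate variables must lie in [0, 1]")
        if np.any(self.q[16:25] < -1e-9):
            raise ValueError("concentrations must be non-negative")
        if self.q[25] < -1e-9 or self.q[25] > 1 + 1e-9:
            raise ValueError("pacemaker gate must lie in [0, 1]")

    def copy(self) -> "CellState":
        return CellState(self.v, self.q.copy())


#: quiescent equilibrium of the default parameter set (30 s unstimulated
#: relaxation, dt = 0.05 ms); total ionic current there is ~5e-6 uA/uF
REST_V = -87.73553817311145
REST_Q = np.array([
    9.7809688601e-04,   # xm
    9.9180859200e-01,   # xh
    9.9457863705e-01,   # xj
    6.4871743613e-03,   # xr
    4.7564481051e-03,   # xs1
    4.7558698381e-03,   # xs2
    3.5085447559e-03,   # xtos
    9.9561433236e-01,   # ytos
    3.5085545405e-03,   # xtof
    9.9560802603e-01,   # ytof
    1.7011036465e-05,   # c1
    9.8540234355e-01,   # c2
    4.0801283428e-06,   # xi1ca
    3.1363652552e-05,   # xi1ba
    1.4936591882e-05,   # xi2ca
    1.4528563937e-02,   # xi2ba
    3.0259966169e-01,   # cp
    1.0892240850e-01,   # cs
    1.0807718899e-01,   # ci
    7.3916883749e+01,   # cj
    7.3984288998e+01,   # cjp
    1.0414226055e-03,   # xir
    1.0987083796e+01,   # nai
    1.0696936254e+01,   # tropi
    1.0768033050e+01,   # trops
    9.3230133959e-01,   # yf (sigmoid equilibrium at REST_V)
])


def rest_state() -> CellState:
    """Quiescent equilibrium state of the ventricular model."""
    return CellState(REST_V, REST_Q.copy())


# ----------------------------------------------------------------------------
# model constants that are not exposed in CellParameters (internal to the
# published formulation; see docs/methods.md)
# ----------------------------------------------------------------------------
_PRNAK = 0.01833      # Na/K permeability ratio in E_Ks
_PCA = 0.00054        # L-type channel Ca permeability, cm/s
_WCA = 8.0313         # uM/ms flux  <->  uA/uF current conversion
_GLEAK = 2.069e-5     # SR leak conductance
_KJ = 50.0            # SR leak half-saturation, uM
_CUP = 0.5            # uptake half-saturation, uM
_XKDNA = 0.3          # exchanger allosteric Ca site, uM
_XMCAO = 1.3
_XMNAO = 87.5
_XMNAI = 12.3
_XMCAI = 0.0036
_XKMKO = 1.5          # pump K half-saturation, mM
_XKMNAI = 12.0        # pump Na half-saturation, mM
_GRYR = 2.58079       # spark-rate gain
_GBARSR = 26841.8     # release conductance into the dyad
_GDYAD = 9000.0       # LCC flux gain into the dyad
_AX = 0.3576          # voltage dependence of dyadic release
_AY = 0.05            # voltage dependence of spark rate
_TAUPS = 0.5          # dyad <-> submembrane relaxation, ms
_CAT = 3.0            # Ca-inactivation half-point of the LCC, uM
_CPT = 6.09365        # dyadic Ca scale in LCC recovery, uM
_TAUPO = 1.0          # LCC activation time constant, ms
_R1 = 0.3
_R2 = 3.0
_S1T = 0.00195
_K1T = 0.00413
_K2 = 1.03615e-4
_K2T = 0.00224
_TCA = 78.0329        # base Ca-mode recovery time, ms
# instantaneous cytosolic buffers: calmodulin, SR sites, membrane, sarcolemma
_BCAL, _XKCAL = 24.0, 7.0
_SRMAX, _SRKD = 47.0, 0.6
_BMEM, _KMEM = 15.0, 0.3
_BSAR, _KSAR = 42.0, 13.0
_BTROP = 70.0         # troponin capacity, uM
_XKON, _XKOFF = 0.0327, 0.0196


@njit(cache=True, fastmath=False)
def _eval_cell(v, q, frt, xnao, xki, xko, cao,
               gca, gtos, gtof, gks, gnaca, gkr, gk1, gnak,
               vup, taus, gna, taur, taua, av, cstar,
               xinf, tau, dq):
    """Evaluate all currents and state derivatives of one cell.

    Writes steady states / time constants of the ten HH gates into
    ``xinf``/``tau`` (so callers can apply Rush-Larsen), derivatives of
    every internal state into ``dq`` (gates included, as (xinf-x)/tau),
    and returns the total ionic current density in uA/uF (outward > 0).
    """
    xm, xh, xj = q[0], q[1], q[2]
    xr = q[3]
    xs1, xs2 = q[4], q[5]
    xtos, ytos, xtof, ytof = q[6], q[7], q[8], q[9]
    c1, c2 = q[10], q[11]
    xi1ca, xi1ba, xi2ca, xi2ba = q[12], q[13], q[14], q[15]
    cp, cs, ci = q[16], q[17], q[18]
    cj, cjp, xir = q[19], q[20], q[21]
    nai = q[22]
    tropi, trops = q[23], q[24]

    rtf = 1.0 / frt
    ena = rtf * np.log(xnao / nai)
    ek = rtf * np.log(xko / xki)

    # --- fast sodium -------------------------------------------------------
    if abs(v + 47.13) < 1e-6:
        am = 3.2
    else:
        am = 0.32 * (v + 47.13) / (1.0 - np.exp(-0.1 * (v + 47.13)))
    bm = 0.08 * np.exp(-v / 11.0)
    if v < -40.0:
        ah = 0.135 * np.exp((80.0 + v) / -6.8)
        bh = 3.56 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.35 * v)
        aj = ((-1.2714e5 * np.exp(0.2444 * v) - 3.474e-5 * np.exp(-0.04391 * v))
              * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23))))
        bj = 0.1212 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14)))
    else:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + np.exp((v + 10.66) / -11.1)))
        aj = 0.0
        bj = 0.3 * np.exp(-2.535e-7 * v) / (1.0 + np.exp(-0.1 * (v + 32.0)))
    xina = gna * xh * xj * xm * xm * xm * (v - ena)
    xinf[0] = am / (am + bm); tau[0] = 1.0 / (am + bm)
    xinf[1] = ah / (ah + bh); tau[1] = 1.0 / (ah + bh)
    xinf[2] = aj / (aj + bj); tau[2] = 1.0 / (aj + bj)

    # --- rapid delayed rectifier ------------------------------------------
    if abs(v + 7.0) < 1e-6:
        xkrv1 = 0.00138 / 0.123
    else:
        xkrv1 = 0.00138 * (v + 7.0) / (1.0 - np.exp(-0.123 * (v + 7.0)))
    if abs(v + 10.0) < 1e-6:
        xkrv2 = 0.00061 / 0.145
    else:
        xkrv2 = 0.00061 * (v + 10.0) / (np.exp(0.145 * (v + 10.0)) - 1.0)
    taukr = 1.0 / (xkrv1 + xkrv2)
    xkrinf = 1.0 / (1.0 + np.exp(-(v + 50.0) / 7.5))
    rg = 1.0 / (1.0 + np.exp((v + 33.0) / 22.4))
    xikr = gkr * np.sqrt(xko / 5.4) * xr * rg * (v - ek)
    xinf[3] = xkrinf; tau[3] = taukr

    # --- slow delayed rectifier (Ca-sensitive conductance) ----------------
    eks = rtf * np.log((xko + _PRNAK * xnao) / (xki + _PRNAK * nai))
    xs1ss = 1.0 / (1.0 + np.exp(-(v - 1.5) / 16.7))
    if abs(v + 30.0) < 1e-6:
        tauxs1 = 1.0 / (0.0000719 / 0.148 + 0.000131 / 0.0687)
    else:
        tauxs1 = 1.0 / (0.0000719 * (v + 30.0) / (1.0 - np.exp(-0.148 * (v + 30.0)))
                        + 0.000131 * (v + 30.0) / (np.exp(0.0687 * (v + 30.0)) - 1.0))
    gksx = 0.433 * (1.0 + 0.8 / (1.0 + (0.5 / ci) ** 3))
    xiks = gks * gksx * xs1 * xs2 * (v - eks)
    xinf[4] = xs1ss; tau[4] = tauxs1
    xinf[5] = xs1ss; tau[5] = 4.0 * tauxs1

    # --- transient outward (slow + fast) ----------------------------------
    rt1 = -(v + 3.0) / 15.0
    rt2 = (v + 33.5) / 10.0
    rt3 = (v + 60.0) / 10.0
    xtos_inf = 1.0 / (1.0 + np.exp(rt1))
    ytos_inf = 1.0 / (1.0 + np.exp(rt2))
    rs_inf = 1.0 / (1.0 + np.exp(rt2))
    txs = 9.0 / (1.0 + np.exp(-rt1)) + 0.5
    tys = 3000.0 / (1.0 + np.exp(rt3)) + 30.0
    xitos = gtos * xtos * (ytos + 0.5 * rs_inf) * (v - ek)
    txf = 3.5 * np.exp(-(v / 30.0) * (v / 30.0)) + 1.5
    tyf = 20.0 / (1.0 + np.exp(rt2)) + 20.0
    xitof = gtof * xtof * ytof * (v - ek)
    xito = xitos + xitof
    xinf[6] = xtos_inf; tau[6] = txs
    xinf[7] = ytos_inf; tau[7] = tys
    xinf[8] = xtos_inf; tau[8] = txf
    xinf[9] = ytos_inf; tau[9] = tyf

    # --- inward rectifier --------------------------------------------------
    aki = 1.02 / (1.0 + np.exp(0.2385 * (v - ek - 59.215)))
    bki = ((0.49124 * np.exp(0.08032 * (v - ek + 5.476))
            + np.exp(0.06175 * (v - ek - 594.31)))
           / (1.0 + np.exp(-0.5143 * (v - ek + 4.753))))
    xkin = aki / (aki + bki)
    xik1 = gk1 * np.sqrt(xko / 5.4) * xkin * (v - ek)

    # --- Na/K pump ---------------------------------------------------------
    sigma = (np.exp(xnao / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * v * frt)
                  + 0.0365 * sigma * np.exp(-v * frt))
    xinak = gnak * fnak * (1.0 / (1.0 + xkmnai_over(nai))) * xko / (xko + _XKMKO)

    # --- Na/Ca exchanger (allosteric) --------------------------------------
    csm = cs / 1000.0  # mM
    zw3 = (nai ** 3) * cao * np.exp(v * 0.35 * frt) \
        - (xnao ** 3) * csm * np.exp(v * (0.35 - 1.0) * frt)
    zw4 = 1.0 + 0.2 * np.exp(v * (0.35 - 1.0) * frt)
    aloss = 1.0 / (1.0 + (_XKDNA / cs) ** 3)
    yz1 = _XMCAO * nai ** 3 + (_XMNAO ** 3) * csm
    yz2 = (_XMNAI ** 3) * cao * (1.0 + csm / _XMCAI)
    yz3 = _XMCAI * (xnao ** 3) * (1.0 + (nai / _XMNAI) ** 3)
    yz4 = (nai ** 3) * cao + (xnao ** 3) * csm
    zw8 = yz1 + yz2 + yz3 + yz4
    jnaca = gnaca * aloss * zw3 / (zw4 * zw8)
    xinaca = _WCA * jnaca

    # --- L-type Ca current: GHK driving term evaluated at the dyad ---------
    za = v * 2.0 * frt
    factor1 = 4.0 * _PCA * 96.485 * frt  # 4 pca F^2/(R T), F in C/mmol
    pcam = cp / 1000.0  # mM
    if abs(za) < 0.001:
        rxa = factor1 * (pcam * np.exp(za) - 0.341 * cao) / (2.0 * frt)
    else:
        rxa = v * factor1 * (pcam * np.exp(za) - 0.341 * cao) / (np.exp(za) - 1.0)
    jca = gca * po_of(q) * rxa
    xica = 2.0 * _WCA * jca

    # --- Markov LCC transition rates ---------------------------------------
    poinf = 1.0 / (1.0 + np.exp(-v / 8.0))
    alpha = poinf / _TAUPO
    beta = (1.0 - poinf) / _TAUPO
    fca = 1.0 / (1.0 + (_CAT / cp) ** 3)
    s1 = 0.0182688 * fca
    k1 = 0.024168 * fca
    s2 = s1 * (_R1 / _R2) * (_K2 / k1)
    s2t = _S1T * (_R1 / _R2) * (_K2T / _K1T)
    poi = 1.0 / (1.0 + np.exp(-(v + 40.0) / 3.0))
    k3 = (1.0 - poi) / 3.0
    k3t = k3
    prv = 1.0 - 1.0 / (1.0 + np.exp(-(v + 40.0) / 4.0))
    ps = 1.0 / (1.0 + np.exp(-(v + 40.0) / 11.32))
    recov = 10.0 + 4954.0 * np.exp(v / 15.6)
    tca = _TCA / (1.0 + (cp / _CPT) ** 4) + 0.1
    tauca = (recov - tca) * prv + tca
    tauba = (recov - 450.0) * prv + 450.0
    k5 = (1.0 - ps) / tauca
    k6 = fca * ps / tauca
    k5t = (1.0 - ps) / tauba
    k6t = ps / tauba
    k4 = k3 * (alpha / beta) * (k1 / _K2) * (k5 / k6)
    k4t = k3t * (alpha / beta) * (_K1T / _K2T) * (k5t / k6t)
    po = po_of(q)
    dq[10] = (alpha * c2 + _K2 * xi1ca + _K2T * xi1ba + _R2 * po
              - (beta + _R1 + _K1T + k1) * c1)                    # c1
    dq[11] = (beta * c1 + k5 * xi2ca + k5t * xi2ba
              - (k6 + k6t + alpha) * c2)                          # c2
    dq[12] = k1 * c1 + k4 * xi2ca + s1 * po - (k3 + _K2 + s2) * xi1ca
    dq[13] = _K1T * c1 + k4t * xi2ba + _S1T * po - (k3t + _K2T + s2t) * xi1ba
    dq[14] = k3 * xi1ca + k6 * c2 - (k5 + k4) * xi2ca
    dq[15] = k3t * xi1ba + k6t * c2 - (k5t + k4t) * xi2ba

    # --- SR release ---------------------------------------------------------
    bv = (1.0 - av) * cstar - 50.0
    if cjp < 50.0:
        qr0 = 0.0
    elif cjp < cstar:
        qr0 = cjp - 50.0
    else:
        qr0 = av * cjp + bv
    qr = cj * qr0 / cstar
    sparkv = np.exp(-_AY * (v + 30.0)) / (1.0 + np.exp(-_AY * (v + 30.0)))
    spark_rate = _GRYR * po * np.abs(rxa) * sparkv
    # release and LCC flux seen by the dyad
    relv = np.exp(-_AX * (v + 30.0)) / (1.0 + np.exp(-_AX * (v + 30.0)))
    xirp = po * qr * np.abs(rxa) * _GBARSR * relv
    xicap = po * _GDYAD * np.abs(rxa)
    xiryr = xirp + xicap

    # --- uptake, leak, diffusion, buffering --------------------------------
    jup = vup * ci * ci / (ci * ci + _CUP * _CUP)
    jleak = _GLEAK * (cj * cj / (cj * cj + _KJ * _KJ)) * (cj * 16.667 - ci)
    jd = (cs - ci) / taus
    xbi = _XKON * ci * (_BTROP - tropi) - _XKOFF * tropi
    xbs = _XKON * cs * (_BTROP - trops) - _XKOFF * trops
    dciib = 1.0 / (1.0 + _buff(ci))
    dcsib = 1.0 / (1.0 + _buff(cs))

    dcj = -xir + jup - jleak                          # SR load
    dq[16] = xiryr - (cp - cs) / _TAUPS               # dyad
    dq[17] = dcsib * (50.0 * (xir - jd - jca + jnaca) - xbs)
    dq[18] = dciib * (jd - jup + jleak - xbi)
    dq[19] = dcj
    dq[20] = (cj - cjp) / taua
    dq[21] = spark_rate * qr - xir * (1.0 - taur * dcj / cj) / taur
    dq[22] = -(xina + 3.0 * xinak + 3.0 * xinaca) / (_WCA * 1000.0)
    dq[23] = xbi
    dq[24] = xbs

    for i in range(N_GATES):
        dq[i] = (xinf[i] - q[i]) / tau[i]

    iion = xina + xik1 + xikr + xiks + xito + xinaca + xica + xinak
    return iion


@njit(cache=True)
def po_of(q):
    """Open probability of the Markov L-type channel."""
    return 1.0 - q[10] - q[11] - q[12] - q[13] - q[14] - q[15]


@njit(cache=True)
def xkmnai_over(nai):
    return _XKMNAI / nai


@njit(cache=True)
def _buff(c):
    """Instantaneous-buffer derivative sum at free [Ca] ``c`` (uM)."""
    return (_BCAL * _XKCAL / ((_XKCAL + c) * (_XKCAL + c))
            + _SRMAX * _SRKD / ((_SRKD + c) * (_SRKD + c))
            + _BMEM * _KMEM / ((_KMEM + c) * (_KMEM + c))
            + _BSAR * _KSAR / ((_KSAR + c) * (_KSAR + c)))
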