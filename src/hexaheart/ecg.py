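"""Pseudo-ECG, activation maps, ECG morphology metrics and sustained-
activity (reentry) detection.

The pseudo-ECG at an electrode x_e outside the tissue is the volume
integral of grad(V) . D . grad(1/r) over the myocardial elements only
(1D Purkinje and PMJ elements are excluded), evaluated with the same
Gauss quadrature as the FEM assembly. Units are arbitrary: only shapes,
widths, ratios and signs are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fem import _shape_gradients
from .mesh import HexMesh

DEFAULT_V_STAR = -40.0          # mV, activation threshold
LEAD_LABELS = ("V1", "V2", "V3", "V4", "V5", "V6")


class LeadPlacementError(ValueError):
    """A lead lies inside the myocardial domain (1/r singularity)."""


@dataclass
class LeadSet:
    """Labeled electrode positions (µm), outside the tissue."""

    labels: tuple
    positions: np.ndarray        # (L, 3)

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("lead labels must be unique")
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_leads, 3)")

    def __len__(self) -> int:
        return len(self.labels)


def default_lead_set(mesh: HexMesh, chest_offset: float = 2.0) -> LeadSet:
    """Six precordial-style leads on a 120° anterior arc in the
    mid-ventricular short-axis plane.

    V1 sits over the right ventricle (+x), V6 left lateral (−x), the arc
    passing anterior (−y). ``chest_offset`` scales the arc radius
    relative to the maximal in-plane extent of the mesh.
    """
    center = mesh.nodes.mean(axis=0)
    r_max = np.max(np.linalg.norm(mesh.nodes[:, :2] - center[:2], axis=1))
    radius = chest_offset * r_max
    angles = np.deg2rad(np.linspace(-60.0, -180.0, 6))
    pos = np.column_stack([center[0] + radius * np.cos(angles),
                           center[1] + radius * np.sin(angles),
                           np.full(6, center[2])])
    return LeadSet(LEAD_LABELS, pos)


@dataclass
class EcgTrace:
    """Per-lead pseudo-ECG signals on a shared time axis."""

    times: np.ndarray            # (T,) ms
    signals: np.ndarray          # (T, L) arbitrary units
    labels: tuple

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        self.labels = tuple(self.labels)
        if self.signals.shape != (len(self.times), len(self.labels)):
            raise ValueError("signals must be (n_times, n_leads)")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("non-finite ECG samples")

    def lead(self, label: str) -> np.ndarray:
        return self.signals[:, self.labels.index(label)]


def _leads_inside(mesh: HexMesh, positions: np.ndarray) -> np.ndarray:
    """True per lead if the point falls inside any hexahedral element."""
    lo = mesh.nodes[mesh.elements].min(axis=1)    # (m, 3)
    hi = mesh.nodes[mesh.elements].max(axis=1)
    inside = np.zeros(len(positions), dtype=bool)
    for i, p in enumerate(positions):
        inside[i] = bool(np.any(np.all((lo <= p) & (p <= hi), axis=1)))
    return inside


def lead_field(mesh: HexMesh, sigma: np.ndarray, leads: LeadSet) -> np.ndarray:
    """Per-lead weight vectors w (L, n_nodes) such that the pseudo-ECG is
    the matrix product V @ w.T; quadrature matches the FEM assembly."""
    sigma = np.asarray(getattr(sigma, "tensors", sigma), dtype=float)
    if sigma.shape != (mesh.n_elements, 3, 3):
        raise ValueError("sigma must be (n_elements, 3, 3)")
    if np.any(_leads_inside(mesh, leads.positions)):
        bad = [leads.labels[i] for i in
               np.nonzero(_leads_inside(mesh, leads.positions))[0]]
        raise LeadPlacementError(f"leads inside the domain: {bad}")
    n_vals, d_vals = _shape_gradients()
    X = mesh.nodes[mesh.elements]                           # (m, 8, 3)
    W = np.zeros((len(leads), mesh.n_nodes))
    for gp in range(8):
        dN = d_vals[gp]                                     # (8, 3)
        J = np.einsum("mib,ia->mba", X, dN)                 # (m, 3, 3)
        detJ = np.linalg.det(J)
        Jinv = np.linalg.inv(J)
        G = np.einsum("ia,mab->mib", dN, Jinv)              # (m, 8, 3)
        xq = np.einsum("i,mib->mb", n_vals[gp], X)          # (m, 3)
        GD = np.einsum("mia,mab->mib", G, sigma)            # grad N . D
        for l, p in enumerate(leads.positions):
            d = xq - p[None, :]
            r = np.linalg.norm(d, axis=1)
            grad_inv_r = -d / (r ** 3)[:, None]             # grad(1/r)
            w_el = np.einsum("mib,mb->mi", GD, grad_inv_r) * detJ[:, None]
            np.add.at(W[l], mesh.elements.ravel(), w_el.ravel())
    return W


def pseudo_ecg(times, v_series, sigma, mesh: HexMesh,
               leads: LeadSet | None = None) -> EcgTrace:
    """Pseudo-ECG of a voltage series over the myocardial elements.

    ``v_series`` is (T, n) with n >= mesh.n_nodes; extra columns (1D
    Purkinje DOFs) are ignored — only the 3D elements enter the integral.
    """
    if leads is None:
        leads = default_lead_set(mesh)
    v = np.asarray(v_series, dtype=float)[:, :mesh.n_nodes]
    W = lead_field(mesh, sigma, leads)
    return EcgTrace(times, v @ W.T, leads.labels)


# ---------------------------------------------------------------------------
# activation maps (Eq.-10-style linear interpolation)
# ---------------------------------------------------------------------------

@dataclass
class ActivationMap:
    """First-crossing activation times per node (NaN = never activated)."""

    times: np.ndarray            # (n,) ms
    v_star: float
    reference_time: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        defined = np.isfinite(self.times)
        if np.any(self.times[defined] < self.reference_time - 1e-12):
            raise ValueError("activation before the reference time")

    @property
    def activated_fraction(self) -> float:
        return float(np.mean(np.isfinite(self.times)))


def activation_map(times, v_series, v_star: float = DEFAULT_V_STAR,
                   reference_time: float = 0.0) -> ActivationMap:
    """First upward crossing of ``v_star`` per node, linearly interpolated
    between the bracketing samples. Nodes above threshold at the first
    sample get the first sample time; nodes never crossing get NaN."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(v_series, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time axis must be strictly increasing")
    n = v.shape[1]
    act = np.full(n, np.nan)
    above = v >= v_star
    act[above[0]] = t[0]
    crossing = ~above[:-1] & above[1:]                     # (T-1, n)
    first = np.argmax(crossing, axis=0)
    has = crossing.any(axis=0) & ~above[0]
    idx = first[has]
    v0 = v[idx, has]
    v1 = v[idx + 1, has]
    frac = (v_star - v0) / (v1 - v0)
    act[has] = t[idx] + frac * (t[idx + 1] - t[idx])
    return ActivationMap(act, v_star, reference_time)


# ---------------------------------------------------------------------------
# ECG morphology
# ---------------------------------------------------------------------------

@dataclass
class LeadMorphology:
    qrs_onset: float = np.nan
    qrs_offset: float = np.nan
    qrs_width: float = np.nan
    r_amp: float = np.nan
    s_amp: float = np.nan
    rs_ratio: float = np.nan
    t_amp: float = np.nan
    t_sign: int = 0
    t_rise: float = np.nan
    t_fall: float = np.nan
    flags: tuple = ()


@dataclass
class EcgMorphology:
    """Per-lead morphology plus cross-lead QRS-width statistics."""

    leads: dict                  # label -> LeadMorphology
    qrs_mean: float = np.nan
    qrs_std: float = np.nan


def _lead_morphology(t, s, deriv_frac, blank, t_frac) -> LeadMorphology:
    span = np.ptp(s)
    if span <= 0 or not np.any(np.abs(np.diff(s)) > 0):
        return LeadMorphology(flags=("flat",))
    d = np.abs(np.gradient(s, t))
    thr = deriv_frac * d.max()
    on = np.nonzero(d >= thr)[0]
    # QRS = first contiguous activity cluster of the derivative envelope
    # (clusters separated by > 20 ms of quiescence belong to the T wave)
    gaps = np.nonzero(np.diff(t[on]) > 20.0)[0]
    last = on[gaps[0]] if len(gaps) else on[-1]
    qrs_on, qrs_off = t[on[0]], t[last]
    m = LeadMorphology(qrs_onset=qrs_on, qrs_offset=qrs_off,
                       qrs_width=qrs_off - qrs_on)
    qrs = (t >= qrs_on) & (t <= qrs_off)
    sq = s[qrs]
    tq = t[qrs]
    m.r_amp = float(max(sq.max(), 0.0))
    i_r = int(np.argmax(sq))
    after_r = sq[i_r:]
    m.s_amp = float(max(-after_r.min(), 0.0)) if len(after_r) else 0.0
    m.rs_ratio = m.r_amp / m.s_amp if m.s_amp > 0 else np.inf
    # T wave after a blanking interval
    tw = t >= qrs_off + blank
    if np.sum(tw) >= 3:
        st = s[tw]
        tt = t[tw]
        ref = st[-1]
        dev = st - ref
        i_pk = int(np.argmax(np.abs(dev)))
        peak = dev[i_pk]
        if abs(peak) > 0:
            m.t_amp = float(abs(peak))
            m.t_sign = int(np.sign(peak))
            lvl = t_frac * abs(peak)
            big = np.abs(dev) >= lvl
            i_on = int(np.argmax(big))
            i_off = len(big) - 1 - int(np.argmax(big[::-1]))
            m.t_rise = float(tt[i_pk] - tt[i_on])
            m.t_fall = float(tt[i_off] - tt[i_pk])
        else:
            m.flags = m.flags + ("no_t_wave",)
    else:
        m.flags = m.flags + ("no_t_window",)
    return m


def ecg_morphology(trace: EcgTrace, window=None, deriv_frac: float = 0.05,
                   t_blank: float = 40.0,
                   t_frac: float = 0.1) -> EcgMorphology:
    """QRS/R/S/T metrics per lead over a single-beat window.

    QRS onset/offset come from a threshold (``deriv_frac`` of the maximum)
    on the absolute-derivative envelope; the T wave is the dominant
    deflection after ``t_blank`` ms past the QRS offset, with rise/fall
    measured between ``t_frac``-of-peak level crossings and the peak.
    """
    t = trace.times
    sel = np.ones(len(t), dtype=bool) if window is None else \
        (t >= window[0]) & (t <= window[1])
    if np.sum(sel) < 4:
        raise ValueError("window contains too few samples")
    leads = {}
    for j, lab in enumerate(trace.labels):
        leads[lab] = _lead_morphology(t[sel], trace.signals[sel, j],
                                      deriv_frac, t_blank, t_frac)
    widths = [m.qrs_width for m in leads.values()
              if np.isfinite(m.qrs_width)]
    return EcgMorphology(leads,
                         qrs_mean=float(np.mean(widths)) if widths else np.nan,
                         qrs_std=float(np.std(widths)) if widths else np.nan)


# ---------------------------------------------------------------------------
# sustained activity (reentry / fibrillation proxy)
# ---------------------------------------------------------------------------

@dataclass
class ActivityStats:
    sustained: bool
    min_active_fraction: float
    wavefront_counts: np.ndarray      # per sampled time step
    window: tuple


def detect_sustained_activity(times, v_series, last_stimulus: float,
                              window: float, v_star: float = DEFAULT_V_STAR,
                              floor: float = 0.05,
                              mesh: HexMesh | None = None) -> ActivityStats:
    """True iff the suprathreshold node fraction never falls below
    ``floor`` for the whole ``window`` after the last stimulus.

    With a mesh, also reports the number of distinct suprathreshold
    connected components per sampled step (wavefront-count proxy).
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(v_series, dtype=float)
    if t[-1] < last_stimulus + window - 1e-9:
        raise ValueError("series does not extend a full window beyond "
                         "the last stimulus")
    sel = np.nonzero((t >= last_stimulus) &
                     (t <= last_stimulus + window))[0]
    above = v[sel] >= v_star
    frac = above.mean(axis=1)
    counts = np.zeros(len(sel), dtype=int)
    if mesh is not None:
        import scipy.sparse as sp
        from scipy.sparse.csgraph import connected_components
        from .mesh import _HEX_EDGES
        pairs = mesh.elements[:, _HEX_EDGES].reshape(-1, 2)
        adj = sp.coo_matrix((np.ones(len(pairs)),
                             (pairs[:, 0], pairs[:, 1])),
                            shape=(mesh.n_nodes, mesh.n_nodes)).tocsr()
        adj = adj + adj.T
        for k, row in enumerate(above[:, :mesh.n_nodes]):
            ids = np.nonzero(row)[0]
            if len(ids) == 0:
                continue
            sub = adj[ids][:, ids]
            counts[k], _ = connected_components(sub, directed=False)
    return ActivityStats(bool(frac.min() >= floor), float(frac.min()),
                         counts, (float(t[sel[0]]), float(t[sel[-1]])))
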