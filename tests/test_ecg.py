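"""Pseudo-ECG lead fields, activation maps and morphology metrics."""

import numpy as np
import pytest

from hexaheart.ecg import (EcgTrace, LeadPlacementError, LeadSet,
                           activation_map, default_lead_set,
                           detect_sustained_activity, ecg_morphology,
                           lead_field, pseudo_ecg)
from hexaheart.mesh import build_slab_mesh
from hexaheart.tensors import isotropic_conductivity


def _slab(extent=(800.0, 400.0, 400.0), edge=400.0):
    mesh = build_slab_mesh(extent, edge)
    sigma = isotropic_conductivity(mesh.n_elements, 1.0e5)
    return mesh, sigma


def test_uniform_voltage_gives_null_signal():
    mesh, sigma = _slab()
    leads = LeadSet(("A",), np.array([[5000.0, 200.0, 200.0]]))
    times = np.array([0.0, 1.0, 2.0])
    v = np.full((3, mesh.n_nodes), 23.0)
    trace = pseudo_ecg(times, v, sigma, mesh, leads=leads)
    # exact in theory; numerically zero relative to the lead-field scale
    W = lead_field(mesh, sigma, leads)
    scale = 23.0 * np.abs(W).sum()
    assert np.max(np.abs(trace.signals)) < 1e-12 * scale


def test_lead_field_linearity():
    mesh, sigma = _slab()
    leads = LeadSet(("A",), np.array([[5000.0, 200.0, 200.0]]))
    W = lead_field(mesh, sigma, leads)
    rng = np.random.default_rng(0)
    a, b = rng.normal(size=(2, mesh.n_nodes))
    assert (2 * a + 3 * b) @ W[0] == pytest.approx(
        2 * (a @ W[0]) + 3 * (b @ W[0]), rel=1e-12)


def test_dipole_antisymmetry():
    # voltage step confined to the first element layer: dipole centered at
    # x = 200; electrodes mirrored across that plane see opposite signals
    mesh, sigma = _slab()
    v = np.where(mesh.nodes[:, 0] < 400.0, 0.0, 40.0)[None, :]
    leads = LeadSet(("P", "M"), np.array([[3200.0, 200.0, 200.0],
                                          [-2800.0, 200.0, 200.0]]))
    trace = pseudo_ecg(np.array([0.0]), v, sigma, mesh, leads=leads)
    p, m = trace.signals[0]
    assert p != 0.0
    assert p == pytest.approx(-m, rel=1e-12)


def test_signal_decays_with_distance():
    mesh, sigma = _slab()
    v = np.where(mesh.nodes[:, 0] < 400.0, 0.0, 40.0)[None, :]
    amps = []
    for d in (2000.0, 4000.0, 8000.0):
        leads = LeadSet(("A",), np.array([[d, 200.0, 200.0]]))
        tr = pseudo_ecg(np.array([0.0]), v, sigma, mesh, leads=leads)
        amps.append(abs(tr.signals[0, 0]))
    assert amps[0] > amps[1] > amps[2]
    # far field of a dipole decays like 1/r^2
    r = np.array([2000.0, 4000.0, 8000.0]) - 200.0
    scaled = np.array(amps) * r ** 2
    assert np.ptp(scaled) / scaled.mean() < 0.1


def test_lead_inside_mesh_rejected():
    mesh, sigma = _slab()
    leads = LeadSet(("A",), np.array([[400.0, 200.0, 200.0]]))
    with pytest.raises(LeadPlacementError):
        lead_field(mesh, sigma, leads)


def test_default_lead_set_outside_and_labeled(small_phantom):
    _, mesh = small_phantom
    leads = default_lead_set(mesh)
    assert leads.labels == ("V1", "V2", "V3", "V4", "V5", "V6")
    sigma = isotropic_conductivity(mesh.n_elements, 1.0e5)
    lead_field(mesh, sigma, leads)  # placement valid: no error


def test_activation_map_interpolated_crossing():
    times = np.array([0.0, 1.0, 2.0])
    v = np.array([[-80.0, -80.0, 0.0],
                  [0.0, -80.0, 10.0],
                  [0.0, -80.0, 20.0]]).T.reshape(3, 3).T
    # node 0: crosses -40 between t=0 (-80) and t=1 (0) -> t=0.5
    # node 1: never crosses -> NaN; node 2: above at t=0 -> 0.0
    v = np.column_stack([np.array([-80.0, 0.0, 0.0]),
                         np.array([-80.0, -80.0, -80.0]),
                         np.array([0.0, 10.0, 20.0])])
    amap = activation_map(times, v)
    assert amap.times[0] == pytest.approx(0.5)
    assert np.isnan(amap.times[1])
    assert amap.times[2] == 0.0


def test_activation_map_reference_time():
    times = np.array([10.0, 11.0])
    v = np.array([[-80.0], [0.0]])
    amap = activation_map(times, v, reference_time=10.0)
    # absolute times are kept; the reference travels as metadata
    assert amap.times[0] == pytest.approx(10.5)
    assert amap.reference_time == 10.0
    with pytest.raises(ValueError):
        activation_map(times, v, reference_time=20.0)


def test_activation_map_rejects_bad_time_axis():
    with pytest.raises(ValueError):
        activation_map(np.array([0.0, 0.0]), np.zeros((2, 1)))


def _triangle_trace():
    t = np.arange(0.0, 200.0, 1.0)
    s = np.zeros_like(t)
    up = (t >= 10) & (t <= 20)
    dn = (t > 20) & (t <= 30)
    s[up] = 10.0 * (t[up] - 10)
    s[dn] = 100.0 - 10.0 * (t[dn] - 20)
    # asymmetric positive T: slow rise 90-140, fast fall 140-150
    tw = (t >= 90) & (t <= 140)
    s[tw] = 20.0 * (t[tw] - 90) / 50.0
    tf = (t > 140) & (t <= 150)
    s[tf] = 20.0 * (150 - t[tf]) / 10.0
    return EcgTrace(t, s[:, None], ("L",))


def test_morphology_triangular_qrs():
    m = ecg_morphology(_triangle_trace()).leads["L"]
    assert m.r_amp == pytest.approx(100.0)
    assert 15.0 <= m.qrs_width <= 25.0
    assert m.t_sign > 0
    assert m.t_amp == pytest.approx(20.0, rel=0.05)
    assert m.t_rise > m.t_fall


def test_morphology_scale_equivariant():
    tr = _triangle_trace()
    big = EcgTrace(tr.times, 7.5 * tr.signals, tr.labels)
    a = ecg_morphology(tr).leads["L"]
    b = ecg_morphology(big).leads["L"]
    assert b.r_amp == pytest.approx(7.5 * a.r_amp)
    assert b.qrs_width == pytest.approx(a.qrs_width)
    assert b.t_sign == a.t_sign


def test_morphology_flat_flagged():
    t = np.arange(0.0, 100.0, 1.0)
    m = ecg_morphology(EcgTrace(t, np.zeros((len(t), 1)), ("L",)))
    assert "flat" in m.leads["L"].flags


def test_sustained_activity_bounds():
    times = np.arange(0.0, 50.0, 1.0)
    n = 20
    v = np.full((len(times), n), -80.0)
    v[:, :4] = 0.0               # 20% permanently active
    stats = detect_sustained_activity(times, v, 0.0, 40.0)
    assert stats.sustained
    assert stats.min_active_fraction == pytest.approx(0.2)
    dead = np.full_like(v, -80.0)
    assert not detect_sustained_activity(times, dead, 0.0, 40.0).sustained
    with pytest.raises(ValueError):
        detect_sustained_activity(times, v, 0.0, 100.0)  # window too long


def test_ecg_trace_validation():
    with pytest.raises(ValueError):
        EcgTrace(np.array([0.0, 1.0]), np.array([[np.nan], [0.0]]), ("L",))
    with pytest.raises(ValueError):
        LeadSet(("A", "A"), np.zeros((2, 3)))
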