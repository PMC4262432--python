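"""Membrane models: rest stability, action potentials, regional rules."""

import numpy as np
import pytest

from hexaheart.cells import (CellState, N_STATES, StimulusSpec,
                             VENTRICULAR_MULT, evaluate_rates,
                             integrate_cell, measure_apd,
                             peak_ito_under_clamp, steady_state_apd)
from hexaheart.cells.backends import (MahajanBackend, PassiveBackend,
                                      TwoVarBackend)
from hexaheart.cells.mahajan import REST_V, rest_state
from hexaheart.cells import twovar


def test_rest_state_is_stationary():
    dv, dq, iion = evaluate_rates(rest_state())
    assert abs(dv) < 1e-2                       # mV/ms
    assert np.max(np.abs(dq)) < 1e-2


def test_rest_state_stable_under_integration():
    spec = StimulusSpec(amplitude=0.0, duration=1.0, cycle_length=200.0,
                        n_beats=1)
    t, v, _, _ = integrate_cell(None, spec, dt=0.05)
    assert np.max(np.abs(v - REST_V)) < 0.5


def test_action_potential_shape():
    spec = StimulusSpec(cycle_length=400.0, n_beats=2)
    t, v, cai, _ = integrate_cell(None, spec, dt=0.05)
    assert v.max() > 10.0                       # overshoot
    assert v.min() < -80.0
    apds, _ = measure_apd(t, v)
    assert len(apds) == 1
    assert 100.0 < apds[0] < 300.0
    assert cai.max() > cai.min()                # calcium transient present


def test_measure_apd_synthetic_trace():
    t = np.linspace(0.0, 400.0, 4001)
    v = np.where((t >= 10.0) & (t < 210.0), 20.0, -80.0)
    apds, _ = measure_apd(t, v)
    assert len(apds) == 1
    assert apds[0] == pytest.approx(200.0, abs=1.0)


def test_gks_multiplier_shortens_apd():
    base = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 0.0])
    fast = np.array([1.0, 8.0, 1.0, 1.0, 1.0, 0.0])
    apd_base = steady_state_apd(mult=base, n_beats=3)
    apd_fast = steady_state_apd(mult=fast, n_beats=3)
    assert apd_fast < apd_base - 5.0


def test_peak_ito_scales_with_gto_mult():
    p1 = peak_ito_under_clamp(1.0)
    p085 = peak_ito_under_clamp(0.85)
    assert p1 > 0
    assert p085 / p1 == pytest.approx(0.85, rel=1e-6)


def test_state_vector_size_checked():
    with pytest.raises(ValueError):
        CellState(REST_V, np.zeros(N_STATES - 1))


def test_backend_interface_consistency():
    for backend in (MahajanBackend(), TwoVarBackend(), PassiveBackend()):
        n = 4
        V = np.full(n, backend.rest_v)
        Q = np.tile(backend.rest_q(), (n, 1))
        iion = np.zeros(n)
        mult = np.tile(VENTRICULAR_MULT, (n, 1))
        backend.step(V, Q, 0.01, mult, iion)
        assert Q.shape == (n, backend.n_states)
        assert np.all(np.isfinite(iion))


def test_passive_backend_zero_current():
    b = PassiveBackend()
    V = np.array([0.0, 50.0, -80.0])
    Q = np.zeros((3, 1))
    iion = np.full(3, 99.0)
    b.step(V, Q, 0.1, np.tile(VENTRICULAR_MULT, (3, 1)), iion)
    assert np.all(iion == 0.0)


def test_twovar_kernel_matches_rhs():
    v, w = 0.3, 0.05
    dv, dw = twovar.rhs(v, w)
    V = np.array([v])
    Q = np.array([[w]])
    iion = np.zeros(1)
    twovar.step_states(V, Q, 0.01, np.tile(VENTRICULAR_MULT, (1, 1)),
                       twovar.DEFAULT_PV, iion)
    assert -iion[0] == pytest.approx(dv)
    assert (Q[0, 0] - w) / 0.01 == pytest.approx(dw)
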