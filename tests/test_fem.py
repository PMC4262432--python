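"""FEM assembly and operator-splitting solver."""

import numpy as np
import pytest

from hexaheart.cells.backends import PassiveBackend, TwoVarBackend
from hexaheart.cells.kernel import VENTRICULAR_MULT
from hexaheart.fem import (AssemblyError, NotActivatedError, SolverConfig,
                           TissueStimulus, assemble, initial_state,
                           measure_cv, run_simulation)
from hexaheart.mesh import build_slab_mesh
from hexaheart.tensors import ConductivityField, isotropic_conductivity


def test_stiffness_annihilates_constants(tiny_system):
    ones = np.ones(tiny_system.n_nodes)
    assert np.max(np.abs(tiny_system.stiffness @ ones)) < 1e-9 * \
        np.abs(tiny_system.stiffness.data).max()


def test_stiffness_symmetric_psd(tiny_system):
    K = tiny_system.stiffness
    asym = (K - K.T).tocoo()
    assert (np.max(np.abs(asym.data)) if asym.nnz else 0.0) < 1e-9
    w = np.linalg.eigvalsh(K.toarray())
    assert w.min() > -1e-9 * w.max()


def test_mass_lump_equals_scaled_volume(tiny_slab, tiny_system):
    # total lumped capacitance = cm * beta * domain volume
    vol = 300.0 * 200.0 * 200.0
    assert tiny_system.c_lump.sum() == pytest.approx(
        tiny_system.cm * tiny_system.beta * vol, rel=1e-12)
    assert np.all(tiny_system.c_lump > 0)
    # consistent mass rows sum to the unscaled lumped mass
    assert np.allclose(np.asarray(tiny_system.mass.sum(axis=1)).ravel(),
                       tiny_system.mass_lump)


def test_assemble_rejects_bad_sigma(tiny_slab):
    with pytest.raises(AssemblyError):
        assemble(tiny_slab, isotropic_conductivity(
            tiny_slab.n_elements + 1, 1.0))
    neg = ConductivityField(np.broadcast_to(
        -np.eye(3), (tiny_slab.n_elements, 3, 3)).copy())
    with pytest.raises(AssemblyError):
        assemble(tiny_slab, neg)


def test_uniform_state_is_diffusion_invariant(tiny_system):
    # null-space property after time discretization: a spatially uniform
    # field produces no diffusion currents
    stim_free = run_simulation(tiny_system, [], 5.0,
                               SolverConfig(dt_pde=0.5, dt_ode=0.5),
                               backend=PassiveBackend())
    v0 = stim_free.V_series[0]
    assert np.allclose(stim_free.V_series[-1], v0, atol=1e-12)


def test_diffusion_conserves_total_charge(tiny_system):
    rng = np.random.default_rng(0)
    state = initial_state(tiny_system.n_nodes, PassiveBackend())
    state.V[:] = rng.normal(size=tiny_system.n_nodes)
    total0 = float(tiny_system.c_lump @ state.V)
    for theta in (1.0, 0.5):
        st = state.copy()
        res = run_simulation(tiny_system, [], 10.0,
                             SolverConfig(dt_pde=0.5, dt_ode=0.5,
                                          theta=theta),
                             backend=PassiveBackend(), state=st)
        total = float(tiny_system.c_lump @ res.V_series[-1])
        assert total == pytest.approx(total0, rel=1e-9)
    # and the field relaxes toward its conserved mean
    mean = total0 / tiny_system.c_lump.sum()
    spread0 = np.ptp(state.V)
    res = run_simulation(tiny_system, [], 50.0,
                         SolverConfig(dt_pde=0.5, dt_ode=0.5),
                         backend=PassiveBackend(), state=state.copy())
    assert np.ptp(res.V_series[-1]) < 0.2 * spread0
    assert np.allclose(res.V_series[-1].mean(), mean, atol=0.1)


def test_stimulus_periodic_window():
    s = TissueStimulus(np.array([0]), onset=5.0, duration=2.0,
                       cycle_length=100.0, n_beats=2)
    assert not s.active(4.9)
    assert s.active(5.0) and s.active(6.9)
    assert not s.active(7.1)
    assert s.active(105.5)
    assert not s.active(205.5)      # only two beats
    with pytest.raises(ValueError):
        TissueStimulus(np.array([]), duration=1.0)
    with pytest.raises(ValueError):
        TissueStimulus(np.array([0]), duration=2.0, cycle_length=1.0)


def test_run_simulation_deterministic(tiny_system):
    stim = [TissueStimulus(np.array([0, 1]), amplitude=2.0, duration=2.0)]
    kwargs = dict(backend=TwoVarBackend(), store_series=True)
    a = run_simulation(tiny_system, stim, 20.0, SolverConfig(
        dt_pde=0.5, dt_ode=0.1), **kwargs)
    b = run_simulation(tiny_system, stim, 20.0, SolverConfig(
        dt_pde=0.5, dt_ode=0.1), **kwargs)
    assert np.array_equal(a.V_series, b.V_series)
    assert np.array_equal(a.activation_times, b.activation_times,
                          equal_nan=True)


def test_plane_wave_activation_ordered():
    mesh = build_slab_mesh((2000.0, 200.0, 200.0), 100.0)
    sigma = isotropic_conductivity(mesh.n_elements, 1.0e5)
    system = assemble(mesh, sigma)
    stim = [TissueStimulus(np.nonzero(mesh.nodes[:, 0] == 0.0)[0],
                           amplitude=2.0, duration=1.0)]
    res = run_simulation(system, stim, 100.0,
                         SolverConfig(dt_pde=0.5, dt_ode=0.1),
                         backend=TwoVarBackend(), activation_threshold=0.5,
                         store_series=False)
    mid = np.nonzero((mesh.nodes[:, 1] == 100.0)
                     & (mesh.nodes[:, 2] == 100.0))[0]
    act = res.activation_times[mid[np.argsort(mesh.nodes[mid, 0])]]
    assert np.all(np.isfinite(act))
    assert np.all(np.diff(act[1:]) > 0)          # monotone past stimulus
    cv = measure_cv(res.activation_times, mesh.nodes,
                    (600.0, 100.0, 100.0), (1400.0, 100.0, 100.0))
    assert cv > 0


def test_measure_cv_requires_activation():
    act = np.array([np.nan, 1.0])
    coords = np.zeros((2, 3))
    coords[1, 0] = 100.0
    with pytest.raises(NotActivatedError):
        measure_cv(act, coords, 0, 1)


def test_strang_matches_godunov_at_small_dt(tiny_system):
    stim = [TissueStimulus(np.array([0, 1, 2]), amplitude=2.0,
                           duration=2.0)]
    res_g = run_simulation(tiny_system, stim, 20.0,
                           SolverConfig(dt_pde=0.05, dt_ode=0.05,
                                        splitting="godunov"),
                           backend=TwoVarBackend())
    res_s = run_simulation(tiny_system, stim, 20.0,
                           SolverConfig(dt_pde=0.05, dt_ode=0.05,
                                        splitting="strang", theta=0.5),
                           backend=TwoVarBackend())
    # both converge to the same trajectory as dt -> 0
    assert np.max(np.abs(res_g.V_series[-1] - res_s.V_series[-1])) < 5e-3
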