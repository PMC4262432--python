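"""Purkinje tree, PMJ coupling and coupled 1D/3D assembly."""

import numpy as np
import pytest

from hexaheart.cells.kernel import PURKINJE_MULT
from hexaheart.purkinje import (DEFAULT_D_PURKINJE, PMJ, PurkinjeTree,
                                assemble_coupled, attach_pmjs,
                                bar_shape_gradients, bar_stiffness,
                                cable_cv, generate_synthetic_tree,
                                straight_cable)
from hexaheart.tensors import isotropic_conductivity


def _y_tree():
    nodes = np.array([[0.0, 0.0, 0.0], [1000.0, 0.0, 0.0],
                      [2000.0, 500.0, 0.0], [2000.0, -500.0, 0.0]])
    segs = np.array([[0, 1], [1, 2], [1, 3]])
    return PurkinjeTree(nodes, segs, root=0)


def test_tree_auto_terminals():
    tree = _y_tree()
    assert sorted(tree.terminals.tolist()) == [2, 3]
    assert tree.area == pytest.approx(np.pi * tree.radius ** 2)


def test_tree_rejects_cycle():
    nodes = np.zeros((3, 3))
    nodes[:, 0] = [0.0, 1.0, 2.0]
    with pytest.raises(ValueError):
        PurkinjeTree(nodes, np.array([[0, 1], [1, 2], [2, 0]]), root=0)


def test_tree_rejects_disconnected():
    nodes = np.zeros((4, 3))
    nodes[:, 0] = [0, 1, 2, 3]
    with pytest.raises(ValueError):
        PurkinjeTree(nodes, np.array([[0, 1], [2, 3], [0, 1]]), root=0)


def test_tree_rejects_zero_length_segment():
    nodes = np.zeros((3, 3))
    nodes[1, 0] = 1.0
    nodes[2, 0] = 1.0          # coincides with node 1
    with pytest.raises(ValueError):
        PurkinjeTree(nodes, np.array([[0, 1], [1, 2]]), root=0)


def test_bar_shape_gradients_partition():
    g, L = bar_shape_gradients(np.zeros(3), np.array([300.0, 400.0, 0.0]))
    assert L == pytest.approx(500.0)
    assert np.allclose(g.sum(axis=0), 0.0)
    assert np.linalg.norm(g[1]) == pytest.approx(1.0 / 500.0)


def test_bar_stiffness_null_space_and_scaling():
    k = bar_stiffness(200.0, 10.0, 5.0)
    assert np.allclose(k @ np.ones(2), 0.0)
    assert k[0, 0] == pytest.approx(5.0 * 10.0 / 200.0)
    assert np.allclose(k, k.T)


def test_pmj_area_conservation_exact(small_phantom):
    _, mesh = small_phantom
    tree = generate_synthetic_tree(mesh, 8, seed=1)
    pmjs = attach_pmjs(tree, mesh, search_radius=600.0)
    for p in pmjs:
        # equal-area split is exact by construction: each branch carries
        # exactly A/k of the cable cross-section
        assert p.branch_area == tree.area / len(p.myo_nodes)
        assert p.total_area == pytest.approx(tree.area, rel=1e-15)


def test_attach_pmjs_fallback_flag(small_phantom):
    _, mesh = small_phantom
    tree = generate_synthetic_tree(mesh, 6, seed=2)
    # zero radius: nothing in range -> nearest endocardial fallback
    pmjs = attach_pmjs(tree, mesh, search_radius=0.0)
    assert all(p.fallback and len(p.myo_nodes) == 1 for p in pmjs)
    pmjs2 = attach_pmjs(tree, mesh, search_radius=600.0)
    assert not any(p.fallback for p in pmjs2)


def test_synthetic_tree_deterministic(small_phantom):
    _, mesh = small_phantom
    a = generate_synthetic_tree(mesh, 10, seed=7)
    b = generate_synthetic_tree(mesh, 10, seed=7)
    c = generate_synthetic_tree(mesh, 10, seed=8)
    assert np.array_equal(a.nodes, b.nodes)
    assert np.array_equal(a.segments, b.segments)
    assert not np.array_equal(a.nodes, c.nodes)


def test_synthetic_tree_terminal_count_and_location(small_phantom):
    _, mesh = small_phantom
    for n in (6, 12):
        tree = generate_synthetic_tree(mesh, n, seed=3)
        assert len(tree.terminals) == n
    # terminals sit on endocardial surface nodes
    tree = generate_synthetic_tree(mesh, 8, seed=3)
    endo = mesh.nodes[np.isin(mesh.surface_tags, ("endo_lv", "endo_rv"))]
    for t in tree.terminals:
        d = np.linalg.norm(endo - tree.nodes[t], axis=1).min()
        assert d < 1e-9


def test_synthetic_tree_min_separation(small_phantom):
    _, mesh = small_phantom
    tree = generate_synthetic_tree(mesh, 10, seed=4, min_separation=1200.0)
    pts = tree.nodes[tree.terminals]
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    assert d.min() >= 1200.0


def test_coupled_assembly_properties(small_phantom):
    _, mesh = small_phantom
    sigma = isotropic_conductivity(mesh.n_elements, 1.0e5)
    tree = generate_synthetic_tree(mesh, 8, seed=1)
    pmjs = attach_pmjs(tree, mesh, search_radius=600.0)
    coupled = assemble_coupled(mesh, sigma, tree, pmjs)
    K = coupled.system.stiffness
    assert coupled.n_total == mesh.n_nodes + tree.n_nodes
    asym = (K - K.T).tocoo()
    scale = np.abs(K.data).max()
    assert (np.max(np.abs(asym.data)) if asym.nnz else 0.0) < 1e-9 * scale
    # conservation across the junctions: constants in the null space
    assert np.max(np.abs(K @ np.ones(coupled.n_total))) < 1e-9 * scale
    # Purkinje DOFs carry the Purkinje surrogate multipliers
    assert np.array_equal(coupled.mult[mesh.n_nodes:],
                          np.tile(PURKINJE_MULT, (tree.n_nodes, 1)))


def test_coupled_rejects_unknown_pmj_nodes(small_phantom):
    _, mesh = small_phantom
    sigma = isotropic_conductivity(mesh.n_elements, 1.0e5)
    tree = generate_synthetic_tree(mesh, 6, seed=1)
    bad = [PMJ(int(tree.terminals[0]), np.array([mesh.n_nodes + 5]),
               tree.area, 200.0, np.array([0.0, 0.0, 1.0]))]
    with pytest.raises(ValueError):
        assemble_coupled(mesh, sigma, tree, bad)


def test_straight_cable_cv_matches_calibration():
    cv = cable_cv(DEFAULT_D_PURKINJE)
    assert cv == pytest.approx(2000.0, rel=0.01)


def test_straight_cable_topology():
    cable = straight_cable(2000.0, 200.0)
    assert cable.n_nodes == 11
    assert sorted(cable.terminals.tolist()) == [10]
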