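"""Tensor lattices, interpolation schemes, conductivity and RMSD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hexaheart.mesh import VoxelMask, build_slab_mesh
from hexaheart.tensors import (OutOfSupportError, TensorLattice,
                               axis_aligned_conductivity,
                               build_conductivity_field, eigenframe,
                               interpolate, invariants_of,
                               isotropic_conductivity, rmsd_fields,
                               synthetic_fiber_lattice)


def _uniform_lattice(t, shape=(3, 3, 3), spacing=100.0):
    tensors = np.broadcast_to(t, shape + (3, 3)).copy()
    return TensorLattice(tensors, spacing=spacing)


def _spd(seed, scale=1.0):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(3, 3))
    return scale * (a @ a.T + 3 * np.eye(3))


def test_invariants_isotropic():
    inv = invariants_of(2.0 * np.eye(3))
    assert inv.trace == pytest.approx(6.0)
    assert inv.fa == 0.0
    assert inv.mode == 0.0


def test_invariants_zero_tensor_flagged():
    inv = invariants_of(np.zeros((3, 3)))
    assert not inv.fa_defined
    assert inv.fa == 0.0


def test_invariants_linear_tensor():
    # single dominant eigenvalue -> FA near 1, mode +1
    inv = invariants_of(np.diag([1.0, 1e-9, 1e-9]))
    assert inv.fa == pytest.approx(1.0, abs=1e-4)
    assert inv.mode == pytest.approx(1.0, abs=1e-4)


def test_invariants_reject_asymmetric():
    t = np.eye(3)
    t[0, 1] = 0.5
    with pytest.raises(ValueError):
        invariants_of(t)


@pytest.mark.parametrize("scheme", ["nearest", "euclidean", "log_euclidean"])
def test_interpolation_reproduces_uniform_field(scheme):
    t = _spd(0)
    lat = _uniform_lattice(t)
    out = interpolate(lat, (120.0, 80.0, 150.0), scheme)
    assert np.allclose(out, t, rtol=1e-10, atol=1e-10)


@pytest.mark.parametrize("scheme", ["nearest", "euclidean", "log_euclidean"])
def test_interpolation_exact_at_lattice_points(scheme):
    rng = np.random.default_rng(1)
    tensors = np.empty((2, 2, 2, 3, 3))
    for idx in np.ndindex(2, 2, 2):
        tensors[idx] = _spd(hash(idx) % 1000)
    lat = TensorLattice(tensors, spacing=100.0)
    out = interpolate(lat, (100.0, 0.0, 100.0), scheme)
    assert np.allclose(out, tensors[1, 0, 1], rtol=1e-9, atol=1e-9)


def test_out_of_support_raises():
    lat = _uniform_lattice(np.eye(3))
    with pytest.raises(OutOfSupportError):
        interpolate(lat, (1e5, 0.0, 0.0), "nearest")


def test_invalid_neighborhood_raises():
    lat = _uniform_lattice(np.eye(3), shape=(2, 2, 2))
    lat.valid[:] = False
    with pytest.raises(OutOfSupportError):
        interpolate(lat, (50.0, 50.0, 50.0), "euclidean")


def test_weights_renormalized_over_valid_neighbors():
    # one valid corner: every scheme must return exactly that tensor
    t = _spd(7)
    tensors = np.broadcast_to(np.eye(3), (2, 2, 2, 3, 3)).copy()
    tensors[1, 1, 1] = t
    valid = np.zeros((2, 2, 2), dtype=bool)
    valid[1, 1, 1] = True
    lat = TensorLattice(tensors, valid=valid, spacing=100.0)
    for scheme in ("nearest", "euclidean", "log_euclidean"):
        assert np.allclose(interpolate(lat, (50.0, 50.0, 50.0), scheme), t)


def test_log_euclidean_preserves_spd_in_interior():
    # Euclidean averaging of SPD tensors can inflate determinants;
    # log-Euclidean interpolation of two SPD tensors must stay SPD
    a, b = _spd(3), _spd(4, scale=0.01)
    tensors = np.stack([np.broadcast_to(a, (2, 2, 3, 3)),
                        np.broadcast_to(b, (2, 2, 3, 3))])
    lat = TensorLattice(tensors, spacing=100.0)
    out = interpolate(lat, (50.0, 50.0, 50.0), "log_euclidean")
    assert np.all(np.linalg.eigvalsh(out) > 0)
    assert np.allclose(out, out.T)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_eigenframe_deterministic_and_orthonormal(seed):
    t = _spd(seed)
    w, u = eigenframe(t)
    assert np.all(np.diff(w) <= 0)          # descending eigenvalues
    assert np.allclose(u @ u.T, np.eye(3), atol=1e-12)
    # sign convention: first nonzero component of each eigenvector positive
    for col in u.T:
        nz = col[np.abs(col) > 1e-12]
        assert nz[0] > 0


def test_axis_aligned_conductivity_ratios():
    f = axis_aligned_conductivity(4, 100.0, fiber_axis=2,
                                  anisotropy=(4.0, 2.0, 1.0))
    assert f.tensors.shape == (4, 3, 3)
    d = np.diagonal(f.tensors[0])
    assert d[2] == pytest.approx(100.0)
    assert sorted(d[:2]) == [pytest.approx(25.0), pytest.approx(50.0)]


def test_build_conductivity_field_orientation_and_ratio():
    # fiber along y everywhere: element tensors must be diag with the
    # largest eigenvalue on y and the configured d_l
    t = np.diag([1.0, 4.0, 2.0]) / 7.0
    lat = _uniform_lattice(t, shape=(8, 8, 8), spacing=100.0)
    mesh = build_slab_mesh((400.0, 400.0, 400.0), 100.0)
    f = build_conductivity_field(mesh, lat, d_l=200.0,
                                 anisotropy=(4.0, 2.0, 1.0))
    for tt in f.tensors[:4]:
        w = np.sort(np.linalg.eigvalsh(tt))[::-1]
        assert w[0] == pytest.approx(200.0)
        assert w[1] == pytest.approx(100.0)
        assert w[2] == pytest.approx(50.0)
        assert tt[1, 1] == pytest.approx(200.0)


def test_build_conductivity_field_out_of_support():
    lat = _uniform_lattice(np.eye(3), shape=(2, 2, 2), spacing=10.0)
    mesh = build_slab_mesh((400.0, 400.0, 400.0), 100.0)
    with pytest.raises(OutOfSupportError):
        build_conductivity_field(mesh, lat)


def test_synthetic_fibers_valid_and_spd():
    occ = np.zeros((8, 8, 8), dtype=bool)
    occ[1:7, 1:7, 1:7] = True
    occ[3:5, 3:5, 3:5] = False          # cavity
    lat = synthetic_fiber_lattice(VoxelMask(occ, 100.0))
    assert lat.valid.sum() > 0
    for idx in np.argwhere(lat.valid)[:20]:
        t = lat.tensors[tuple(idx)]
        assert np.array_equal(t, t.T)   # bitwise symmetric
        assert np.all(np.linalg.eigvalsh(t) > 0)
        assert np.trace(t) == pytest.approx(1.0)


def test_rmsd_identities():
    rng = np.random.default_rng(2)
    a = rng.normal(size=(5, 40))
    assert np.all(rmsd_fields(a, a) == 0.0)
    b = a + 3.0
    assert np.allclose(rmsd_fields(a, b), 3.0)
    # symmetry and scale
    c = rng.normal(size=(5, 40))
    assert np.allclose(rmsd_fields(a, c), rmsd_fields(c, a))
    assert np.allclose(rmsd_fields(2 * a, 2 * c), 2 * rmsd_fields(a, c))


def test_rmsd_shape_mismatch():
    with pytest.raises(ValueError):
        rmsd_fields(np.zeros((2, 3)), np.zeros((2, 4)))


def test_isotropic_conductivity_shape():
    f = isotropic_conductivity(5, 3.0)
    assert f.tensors.shape == (5, 3, 3)
    assert np.allclose(f.tensors[2], 3.0 * np.eye(3))
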