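"""Diffusion-tensor lattices: invariants, interpolation, conductivity-field
construction, synthetic fiber generation and field comparison.

Tensors are symmetric 3x3 arrays. A TensorLattice stores one tensor per
lattice point of a regular grid plus a validity mask; interpolation schemes
operate on the trilinear neighborhood of the query point, renormalizing
weights over the valid neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: default anisotropy ratio of conductivity eigenvalues (fiber : sheet :
#: sheet-normal)
DEFAULT_ANISOTROPY = (4.0, 2.0, 1.0)

SCHEMES = ("nearest", "euclidean", "log_euclidean")


class OutOfSupportError(ValueError):
    """Query point has no valid lattice neighbor."""


@dataclass(frozen=True)
class TensorInvariants:
    trace: float
    fa: float
    mode: float
    fa_defined: bool = True


@dataclass
class TensorLattice:
    """Regular grid of symmetric 3x3 tensors at lattice points
    origin + index * spacing."""

    tensors: np.ndarray          # (nx, ny, nz, 3, 3)
    valid: np.ndarray = None     # (nx, ny, nz) bool
    spacing: np.ndarray = None   # (3,) µm
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.ndim != 5 or self.tensors.shape[3:] != (3, 3):
            raise ValueError("tensors must have shape (nx, ny, nz, 3, 3)")
        if self.valid is None:
            self.valid = np.ones(self.tensors.shape[:3], dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.tensors.shape[:3]:
                raise ValueError("validity mask shape mismatch")
        self.spacing = (np.ones(3) if self.spacing is None
                        else np.asarray(self.spacing, float) * np.ones(3))
        if not np.all(self.spacing > 0):
            raise ValueError("lattice spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=float) * np.ones(3)

    @property
    def shape(self):
        return self.tensors.shape[:3]


def _sym(t: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.shape != (3, 3):
        raise ValueError("tensor must be 3x3")
    if np.abs(t - t.T).max() > tol * max(1.0, np.abs(t).max()):
        raise ValueError("tensor is not symmetric within tolerance")
    return 0.5 * (t + t.T)


def invariants_of(t: np.ndarray) -> TensorInvariants:
    """Trace, fractional anisotropy and mode of a symmetric tensor.

    FA = sqrt(3/2) * ||dev(T)||_F / ||T||_F with dev the deviatoric part;
    mode = 3*sqrt(6) * det(dev(T) / ||dev(T)||_F). For the zero tensor FA is
    undefined and reported as 0 with ``fa_defined`` False; an isotropic
    tensor has FA 0 and mode 0 by convention.
    """
    t = _sym(t)
    tr = float(np.trace(t))
    norm = float(np.linalg.norm(t))
    if norm == 0.0:
        return TensorInvariants(0.0, 0.0, 0.0, fa_defined=False)
    dev = t - (tr / 3.0) * np.eye(3)
    dnorm = float(np.linalg.norm(dev))
    fa = float(np.sqrt(1.5) * dnorm / norm)
    mode = 0.0 if dnorm == 0.0 else float(
        3.0 * np.sqrt(6.0) * np.linalg.det(dev / dnorm))
    return TensorInvariants(tr, min(fa, 1.0), float(np.clip(mode, -1, 1)))


def _logm_spd(t: np.ndarray) -> np.ndarray:
    w, u = np.linalg.eigh(t)
    if np.any(w <= 0):
        raise ValueError("matrix logarithm requires a positive-definite tensor")
    return (u * np.log(w)) @ u.T


def _expm_sym(t: np.ndarray) -> np.ndarray:
    w, u = np.linalg.eigh(t)
    return (u * np.exp(w)) @ u.T


def interpolate(lattice: TensorLattice, point, scheme: str) -> np.ndarray:
    """Interpolated tensor at ``point`` (µm).

    nearest: tensor of the closest valid point of the trilinear
    neighborhood. euclidean: trilinear weights on tensor components.
    log_euclidean: trilinear weights on matrix logarithms, exponentiated.
    Weights are renormalized over the valid neighbors.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    p = np.asarray(point, dtype=float)
    u = (p - lattice.origin) / lattice.spacing
    shape = np.array(lattice.shape)
    if np.any(u < -1e-9) or np.any(u > shape - 1 + 1e-9):
        raise OutOfSupportError(f"point {point} outside lattice domain")
    i0 = np.clip(np.floor(u).astype(int), 0, np.maximum(shape - 2, 0))
    f = u - i0

    corners, weights = [], []
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                idx = i0 + (dx, dy, dz)
                if np.any(idx >= shape):
                    continue
                wgt = ((f[0] if dx else 1 - f[0])
                       * (f[1] if dy else 1 - f[1])
                       * (f[2] if dz else 1 - f[2]))
                if lattice.valid[tuple(idx)]:
                    corners.append(tuple(idx))
                    weights.append(wgt)
    if not corners:
        raise OutOfSupportError(
            f"no valid lattice point in the neighborhood of {point}")
    weights = np.asarray(weights)

    if scheme == "nearest":
        pos = lattice.origin + np.array(corners) * lattice.spacing
        k = int(np.argmin(np.linalg.norm(pos - p, axis=1)))
        return lattice.tensors[corners[k]].copy()
    wsum = weights.sum()
    if wsum <= 0:
        raise OutOfSupportError(
            f"degenerate interpolation weights at {point}")
    weights = weights / wsum
    if scheme == "euclidean":
        out = np.zeros((3, 3))
        for c, w in zip(corners, weights):
            out += w * lattice.tensors[c]
        return out
    acc = np.zeros((3, 3))
    for c, w in zip(corners, weights):
        acc += w * _logm_spd(lattice.tensors[c])
    return _expm_sym(acc)


def _fix_eigvec_signs(u: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector signs: first nonzero component positive."""
    for k in range(u.shape[1]):
        col = u[:, k]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if len(nz) and col[nz[0]] < 0:
            u[:, k] = -col
    return u


def eigenframe(t: np.ndarray):
    """Eigenvalues (descending) and sign-fixed orthonormal eigenvectors."""
    w, u = np.linalg.eigh(_sym(t))
    order = np.argsort(w)[::-1]
    return w[order], _fix_eigvec_signs(u[:, order])


@dataclass
class ConductivityField:
    """One symmetric positive-definite tensor per element (diffusivity form,
    µm²/ms)."""

    tensors: np.ndarray          # (m, 3, 3)

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.ndim != 3 or self.tensors.shape[1:] != (3, 3):
            raise ValueError("conductivity tensors must be (m, 3, 3)")

    @property
    def n_elements(self) -> int:
        return len(self.tensors)


def isotropic_conductivity(n_elements: int, d: float) -> ConductivityField:
    """Uniform isotropic field with diffusivity ``d`` (µm²/ms)."""
    return ConductivityField(np.broadcast_to(
        d * np.eye(3), (n_elements, 3, 3)).copy())


def axis_aligned_conductivity(n_elements: int, d_l: float,
                              fiber_axis: int = 0,
                              anisotropy=DEFAULT_ANISOTROPY) -> ConductivityField:
    """Uniform anisotropic field with the fiber along a coordinate axis."""
    r = np.asarray(anisotropy, float)
    diag = d_l * r / r[0]
    vals = np.empty(3)
    vals[fiber_axis] = diag[0]
    others = [ax for ax in range(3) if ax != fiber_axis]
    vals[others[0]], vals[others[1]] = diag[1], diag[2]
    return ConductivityField(np.broadcast_to(
        np.diag(vals), (n_elements, 3, 3)).copy())


def build_conductivity_field(mesh, lattice: TensorLattice,
                             scheme: str = "log_euclidean",
                             anisotropy=DEFAULT_ANISOTROPY,
                             d_l: float = 100.0) -> ConductivityField:
    """Per-element conductivity from interpolated tensor orientations.

    Only the eigenvector frame of the interpolated tensor is used; the
    eigenvalues are replaced by ``d_l`` scaled by the configured anisotropy
    ratio: sigma = R diag(d_l, d_l*r2/r1, d_l*r3/r1) R^T. Sampling is at
    element centroids.
    """
    r = np.asarray(anisotropy, dtype=float)
    if r.shape != (3,) or np.any(r <= 0):
        raise ValueError("anisotropy ratio must be three positive numbers")
    if not d_l > 0:
        raise ValueError("longitudinal diffusivity must be positive")
    diag = d_l * r / r[0]
    out = np.empty((mesh.n_elements, 3, 3))
    failures = []
    for i, c in enumerate(mesh.element_centroids()):
        try:
            t = interpolate(lattice, c, scheme)
        except OutOfSupportError:
            failures.append(i)
            continue
        _, rot = eigenframe(t)
        out[i] = (rot * diag) @ rot.T
    if failures:
        raise OutOfSupportError(
            f"{len(failures)} element centroids outside lattice support "
            f"(first few: {failures[:5]})")
    return ConductivityField(out)


# ---------------------------------------------------------------------------
# synthetic fibers
# ---------------------------------------------------------------------------

def synthetic_fiber_lattice(mask, helix_endo_deg: float = 60.0,
                            helix_epi_deg: float = -60.0,
                            eigenvalues=(4.0, 2.0, 1.0)) -> TensorLattice:
    """Rule-based transmurally rotating fiber field on a myocardial mask.

    The fiber (primary eigenvector) lies in the plane tangent to the wall,
    rotated from the circumferential direction by a helix angle that varies
    linearly with normalized wall depth from ``helix_endo_deg`` at the
    endocardium to ``helix_epi_deg`` at the epicardium. The third eigenvector
    is the local wall normal. Tensors are unit-trace with the given
    eigenvalue ratio; voxels outside the mask (or with a degenerate local
    frame) are marked invalid.
    """
    from scipy import ndimage

    occ = np.asarray(mask.occupancy, dtype=bool)
    spacing = mask.spacing
    empty = ~occ
    # empty-space components touching the array border are "outside"; the
    # rest are cavities (endocardial side)
    lab, n = ndimage.label(empty)
    border = set()
    for ax in range(3):
        border.update(np.unique(np.take(lab, [0, -1], axis=ax)))
    border.discard(0)
    outside = np.isin(lab, sorted(border))
    cavity = empty & ~outside

    d_endo = ndimage.distance_transform_edt(~cavity, sampling=spacing)
    d_epi = ndimage.distance_transform_edt(~outside, sampling=spacing)
    with np.errstate(invalid="ignore"):
        depth = d_endo / (d_endo + d_epi)
    depth = np.nan_to_num(depth, nan=0.5)
    # wall normal from the gradient of the signed wall coordinate
    phi = d_endo - d_epi
    grad = np.stack(np.gradient(phi, *spacing), axis=-1)

    shape = occ.shape
    tensors = np.zeros(shape + (3, 3))
    validg = np.zeros(shape, dtype=bool)
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam / lam.sum()
    zhat = np.array([0.0, 0.0, 1.0])
    h0, h1 = np.deg2rad(helix_endo_deg), np.deg2rad(helix_epi_deg)

    idx = np.argwhere(occ)
    for i, j, k in idx:
        n_vec = grad[i, j, k]
        nn = np.linalg.norm(n_vec)
        if nn < 1e-12:
            continue
        n_vec = n_vec / nn
        circ = np.cross(zhat, n_vec)
        cn = np.linalg.norm(circ)
        if cn < 1e-8:          # wall normal parallel to the long axis
            continue
        circ = circ / cn
        longit = np.cross(n_vec, circ)
        ang = h0 + (h1 - h0) * depth[i, j, k]
        fiber = np.cos(ang) * circ + np.sin(ang) * longit
        sheet = np.cross(n_vec, fiber)
        rot = np.column_stack([fiber, sheet, n_vec])
        t = (rot * lam) @ rot.T
        # enforce bitwise symmetry (matmul leaves ulp-level asymmetry)
        tensors[i, j, k] = 0.5 * (t + t.T)
        validg[i, j, k] = True
    return TensorLattice(tensors, validg, spacing,
                         np.asarray(mask.origin) + 0.5 * spacing)


def rmsd_fields(run_a: np.ndarray, run_b: np.ndarray) -> np.ndarray:
    """Root-mean-square deviation over nodes, per time step (mV).

    Inputs are (timesteps, nodes) arrays on the same mesh and sampling.
    """
    a = np.asarray(run_a, dtype=float)
    b = np.asarray(run_b, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if b.ndim == 1:
        b = b[None, :]
    if a.shape != b.shape:
        raise ValueError(f"field shapes differ: {a.shape} vs {b.shape}")
    return np.sqrt(np.mean((a - b) ** 2, axis=1))
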