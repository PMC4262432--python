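"""Voxel masks, stair-stepped hexahedral meshes, slabs and the labeled
biventricular phantom.

Coordinate convention: right-handed, µm units, apex at minimum z, base at
maximum z. Element connectivity uses the standard 8-node hexahedron ordering
(bottom face counter-clockwise, then top face), giving positive Jacobians on
all axis-aligned elements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: node surface tags
TAG_NONE = ""
TAG_ENDO_LV = "endo_lv"
TAG_ENDO_RV = "endo_rv"
TAG_EPI = "epi"

TRANSMURAL_ZONES = ("endo", "M", "epi")
LONGITUDINAL_ZONES = ("apex", "center", "base")

#: local node offsets (unit cube) in connectivity order
_HEX_OFFSETS = np.array([
    (0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
    (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1),
], dtype=np.int64)

#: the 12 edges of a hexahedron as local node index pairs
_HEX_EDGES = np.array([
    (0, 1), (1, 2), (2, 3), (3, 0),
    (4, 5), (5, 6), (6, 7), (7, 4),
    (0, 4), (1, 5), (2, 6), (3, 7),
], dtype=np.int64)


@dataclass
class VoxelMask:
    """Binary occupancy on a regular voxel grid."""

    occupancy: np.ndarray        # 3D bool
    spacing: np.ndarray          # (3,) µm
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be a 3D array")
        self.spacing = np.asarray(self.spacing, dtype=float) * np.ones(3)
        self.origin = np.asarray(self.origin, dtype=float) * np.ones(3)
        if not np.all(self.spacing > 0):
            raise ValueError("voxel spacing must be positive on every axis")

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())


@dataclass
class HexMesh:
    """3D hexahedral mesh with per-element region labels and per-node
    surface tags."""

    nodes: np.ndarray            # (n, 3) µm
    elements: np.ndarray         # (m, 8) int
    region_labels: np.ndarray = None   # (m,) str, "" = unlabeled
    surface_tags: np.ndarray = None    # (n,) str in {"", endo_lv, endo_rv, epi}

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be (n, 3)")
        if self.elements.ndim != 2 or self.elements.shape[1] != 8:
            raise ValueError("elements must be (m, 8)")
        if not np.all(np.isfinite(self.nodes)):
            raise ValueError("node coordinates must be finite")
        if self.elements.size and (self.elements.min() < 0
                                   or self.elements.max() >= len(self.nodes)):
            raise ValueError("element connectivity references invalid nodes")
        if self.region_labels is None:
            self.region_labels = np.full(len(self.elements), "", dtype="<U16")
        else:
            self.region_labels = np.asarray(self.region_labels, dtype="<U16")
            if self.region_labels.shape != (len(self.elements),):
                raise ValueError("one region label per element required")
        if self.surface_tags is None:
            self.surface_tags = np.full(len(self.nodes), "", dtype="<U16")
        else:
            self.surface_tags = np.asarray(self.surface_tags, dtype="<U16")
            if self.surface_tags.shape != (len(self.nodes),):
                raise ValueError("one surface tag per node required")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)


@dataclass(frozen=True)
class MeshStats:
    """Edge-length statistics (µm) and entity counts."""

    min_edge: float
    median_edge: float
    max_edge: float
    n_elements: int
    n_nodes: int

    def __post_init__(self) -> None:
        if not self.min_edge <= self.median_edge <= self.max_edge:
            raise ValueError("edge statistics must satisfy min <= median <= max")


def _grid_mesh(xs: np.ndarray, ys: np.ndarray, zs: np.ndarray,
               occupied: np.ndarray | None = None) -> HexMesh:
    """Structured hex mesh from node coordinate vectors; ``occupied`` is an
    optional (nx-1, ny-1, nz-1) bool cell selector. Unused nodes are dropped
    and node numbering is deterministic (x fastest)."""
    nx, ny, nz = len(xs), len(ys), len(zs)
    cx, cy, cz = nx - 1, ny - 1, nz - 1
    if occupied is None:
        occupied = np.ones((cx, cy, cz), dtype=bool)
    ci, cj, ck = np.nonzero(occupied)
    if len(ci) == 0:
        raise ValueError("no occupied voxels to mesh")

    def nid(i, j, k):
        return (k * ny + j) * nx + i

    conn = np.empty((len(ci), 8), dtype=np.int64)
    for a, (di, dj, dk) in enumerate(_HEX_OFFSETS):
        conn[:, a] = nid(ci + di, cj + dj, ck + dk)
    used, inv = np.unique(conn, return_inverse=True)
    conn = inv.reshape(conn.shape)
    gi = used % nx
    gj = (used // nx) % ny
    gk = used // (nx * ny)
    nodes = np.column_stack([xs[gi], ys[gj], zs[gk]])
    return HexMesh(nodes, conn)


def build_stair_stepped_mesh(mask: VoxelMask, edge: float) -> HexMesh:
    """One hexahedral element per occupied voxel after nearest-neighbor
    resampling of the mask to cubic voxels of size ``edge`` (µm)."""
    if not edge > 0:
        raise ValueError("edge length must be positive")
    if mask.n_occupied == 0:
        raise ValueError("mask has no occupied voxels")
    shape = np.array(mask.occupancy.shape)
    extent = shape * mask.spacing
    new_shape = np.maximum(1, np.round(extent / edge).astype(int))
    if np.allclose(mask.spacing, edge) and np.all(new_shape == shape):
        occ = mask.occupancy
    else:
        idx = []
        for ax in range(3):
            centers = (np.arange(new_shape[ax]) + 0.5) * edge
            idx.append(np.clip((centers / mask.spacing[ax]).astype(int),
                               0, shape[ax] - 1))
        occ = mask.occupancy[np.ix_(*idx)]
    if not occ.any():
        raise ValueError("resampled mask has no occupied voxels")
    xs = mask.origin[0] + edge * np.arange(occ.shape[0] + 1)
    ys = mask.origin[1] + edge * np.arange(occ.shape[1] + 1)
    zs = mask.origin[2] + edge * np.arange(occ.shape[2] + 1)
    return _grid_mesh(xs, ys, zs, occ)


def _axis_coords(length: float, spec, axis_name: str) -> np.ndarray:
    """Node coordinates along one axis from a scalar edge or edge sequence.

    A sequence is cycled until the extent is filled; if the extent is not
    met exactly the last cell is adjusted (warning) unless the mismatch
    exceeds one cell.
    """
    if np.isscalar(spec):
        edge = float(spec)
        if edge <= 0:
            raise ValueError("edge length must be positive")
        n = max(1, int(round(length / edge)))
        if abs(n * edge - length) > 1e-6:
            warnings.warn(
                f"{axis_name} extent {length} not divisible by edge {edge}; "
                f"using {n} cells of {length / n:.6g} um", stacklevel=3)
        return np.linspace(0.0, length, n + 1)
    seq = [float(e) for e in spec]
    if not seq or any(e <= 0 for e in seq):
        raise ValueError("graded edge sequence must be positive and non-empty")
    edges = []
    total = 0.0
    i = 0
    while total < length - 1e-9:
        e = seq[i % len(seq)]
        if total + e > length + 1e-9:
            break
        edges.append(e)
        total += e
        i += 1
    rem = length - total
    if rem > 1e-6:
        if edges and rem > max(seq) + 1e-9:
            raise ValueError("graded sequence cannot fill the extent")
        warnings.warn(
            f"{axis_name} extent adjusted: final cell of {rem:.6g} um added",
            stacklevel=3)
        edges.append(rem)
    if not edges:
        edges = [length]
    return np.concatenate([[0.0], np.cumsum(edges)])


def build_slab_mesh(extent, edge) -> HexMesh:
    """Structured slab of the given extent (µm triple).

    ``edge`` is a scalar (uniform mesh) or a dict with per-axis entries
    (``x``/``y``/``z``), each a scalar or a graded edge sequence that is
    cycled along the axis.
    """
    extent = np.asarray(extent, dtype=float)
    if extent.shape != (3,) or not np.all(extent > 0):
        raise ValueError("extent must be a positive (x, y, z) triple in um")
    if isinstance(edge, dict):
        unknown = set(edge) - {"x", "y", "z"}
        if unknown:
            raise ValueError(f"unknown axes in edge spec: {sorted(unknown)}")
        specs = [edge.get(ax, min(_flat(edge))) for ax in ("x", "y", "z")]
    else:
        specs = [edge, edge, edge]
    xs = _axis_coords(extent[0], specs[0], "x")
    ys = _axis_coords(extent[1], specs[1], "y")
    zs = _axis_coords(extent[2], specs[2], "z")
    return _grid_mesh(xs, ys, zs)


def _flat(edge_dict):
    out = []
    for v in edge_dict.values():
        out.extend([v] if np.isscalar(v) else list(v))
    return out


def mesh_edge_stats(mesh: HexMesh) -> MeshStats:
    """Edge-length statistics over unique element edges."""
    if mesh.n_elements == 0:
        raise ValueError("mesh has no elements")
    pairs = mesh.elements[:, _HEX_EDGES]          # (m, 12, 2)
    pairs = pairs.reshape(-1, 2)
    pairs = np.sort(pairs, axis=1)
    pairs = np.unique(pairs, axis=0)
    d = np.linalg.norm(mesh.nodes[pairs[:, 0]] - mesh.nodes[pairs[:, 1]],
                       axis=1)
    return MeshStats(float(d.min()), float(np.median(d)), float(d.max()),
                     mesh.n_elements, mesh.n_nodes)


# ---------------------------------------------------------------------------
# biventricular phantom
# ---------------------------------------------------------------------------

def _inside_ellipsoid(pts, center, semi):
    r = (pts - center) / semi
    return np.einsum("ij,ij->i", r, r) < 1.0


def build_biventricular_phantom(outer_radii=(8000.0, 8000.0, 12000.0),
                                wall_thickness: float = 2400.0,
                                septum_thickness: float = 2400.0,
                                base_height: float = 4000.0,
                                edge: float = 400.0):
    """Two-cavity truncated-ellipsoid myocardial shell.

    The epicardium is the ellipsoid with semi-axes ``outer_radii`` centered
    at the origin; the endocardium is the same ellipsoid shrunk by
    ``wall_thickness``; the inner cavity is split into LV (x < 0 side) and RV
    (x > 0 side) by a septal slab of thickness ``septum_thickness``. The
    shell is truncated at z = ``base_height`` (apex at z = -outer_radii[2]).
    Returns ``(mask, mesh)`` with LV-endo / RV-endo / epi surface tags.
    """
    a, b, c = (float(r) for r in outer_radii)
    w, s, e = float(wall_thickness), float(septum_thickness), float(edge)
    if min(a, b, c) <= 0 or e <= 0:
        raise ValueError("radii and edge must be positive")
    if w < 3 * e:
        raise ValueError("wall thickness must be at least 3 element edges")
    if w >= min(a, b, c):
        raise ValueError("wall thickness leaves no cavity")
    if s >= 2 * (a - w):
        raise ValueError("septum thickness leaves no room for two cavities")
    if not (-c < base_height <= c):
        raise ValueError("base truncation height outside the ellipsoid")

    center = np.zeros(3)
    outer = np.array([a, b, c])
    inner = outer - w

    # voxel grid covering the truncated ellipsoid
    lo = np.array([-a, -b, -c])
    hi = np.array([a, b, min(c, base_height)])
    shape = np.ceil((hi - lo) / e).astype(int)
    origin = lo
    ii = np.indices(shape).reshape(3, -1).T
    centers = origin + (ii + 0.5) * e

    in_outer = _inside_ellipsoid(centers, center, outer)
    in_inner = _inside_ellipsoid(centers, center, inner)
    below_base = centers[:, 2] < base_height
    septal = np.abs(centers[:, 0]) <= s / 2.0
    cavity = in_inner & ~septal
    lv_cavity = cavity & (centers[:, 0] < 0)
    rv_cavity = cavity & (centers[:, 0] > 0)
    myo = in_outer & below_base & ~cavity

    occ = myo.reshape(shape)
    if not occ.any():
        raise ValueError("phantom parameters produce an empty myocardium")
    mask = VoxelMask(occ, np.full(3, e), origin)
    mesh = build_stair_stepped_mesh(mask, e)

    # classify exposed faces by the emptiness class of the neighbor voxel
    lv = lv_cavity.reshape(shape)
    rv = rv_cavity.reshape(shape)
    _tag_surface_nodes(mesh, occ, lv, rv, origin, e)
    return mask, mesh


def _tag_surface_nodes(mesh: HexMesh, occ, lv_cavity, rv_cavity,
                       origin, edge) -> None:
    """Set node surface tags from voxel-face exposure.

    A face of an occupied voxel exposed to an LV(RV)-cavity voxel tags its
    four nodes endocardial-LV(RV); exposure to anything else (outside or
    base cut) tags them epicardial. Priority endo_lv > endo_rv > epi keeps
    exactly one tag per surface node.
    """
    shape = occ.shape
    # voxel index of each element from its minimum corner
    emin = mesh.nodes[mesh.elements].min(axis=1)
    vox = np.round((emin - origin) / edge).astype(int)

    score = np.zeros(mesh.n_nodes, dtype=np.int8)  # 0 none,1 epi,2 rv,3 lv
    # local node indices of the face normal to axis ax, low/high side
    faces = {
        (0, -1): (0, 3, 7, 4), (0, +1): (1, 2, 6, 5),
        (1, -1): (0, 1, 5, 4), (1, +1): (3, 2, 6, 7),
        (2, -1): (0, 1, 2, 3), (2, +1): (4, 5, 6, 7),
    }
    pad = np.pad(occ, 1, constant_values=False)
    lv = np.pad(lv_cavity, 1, constant_values=False)
    rv = np.pad(rv_cavity, 1, constant_values=False)
    p = vox + 1
    for (ax, sgn), locs in faces.items():
        q = p.copy()
        q[:, ax] += sgn
        nb_occ = pad[q[:, 0], q[:, 1], q[:, 2]]
        exposed = ~nb_occ
        if not exposed.any():
            continue
        nb_lv = lv[q[:, 0], q[:, 1], q[:, 2]]
        nb_rv = rv[q[:, 0], q[:, 1], q[:, 2]]
        cls = np.where(nb_lv, 3, np.where(nb_rv, 2, 1)).astype(np.int8)
        for loc in locs:
            nid = mesh.elements[exposed, loc]
            np.maximum.at(score, nid, cls[exposed])
    tags = np.array([TAG_NONE, TAG_EPI, TAG_ENDO_RV, TAG_ENDO_LV])
    mesh.surface_tags[:] = tags[score]


def assign_nine_regions(mesh: HexMesh) -> HexMesh:
    """Label every element with one of the nine (endo|M|epi) x
    (apex|center|base) regions, in place.

    Transmural class from normalized wall depth d_endo/(d_endo+d_epi) in
    exact thirds (ties to the lower class); longitudinal class from the z
    coordinate of the element centroid in thirds of the apex-base range.
    Requires endocardial and epicardial surface tags. Idempotent.
    """
    from scipy.spatial import cKDTree

    endo = np.isin(mesh.surface_tags, (TAG_ENDO_LV, TAG_ENDO_RV))
    epi = mesh.surface_tags == TAG_EPI
    if not endo.any() or not epi.any():
        raise ValueError("surface tags (endo and epi) required for labeling")
    cen = mesh.element_centroids()
    d_endo = cKDTree(mesh.nodes[endo]).query(cen)[0]
    d_epi = cKDTree(mesh.nodes[epi]).query(cen)[0]
    depth = d_endo / (d_endo + d_epi)
    zmin, zmax = mesh.nodes[:, 2].min(), mesh.nodes[:, 2].max()
    height = (cen[:, 2] - zmin) / (zmax - zmin)

    def third(x, names):
        cls = np.where(x <= 1.0 / 3.0, 0, np.where(x <= 2.0 / 3.0, 1, 2))
        return np.array(names)[cls]

    tz = third(depth, TRANSMURAL_ZONES)
    lz = third(height, LONGITUDINAL_ZONES)
    mesh.region_labels[:] = np.char.add(np.char.add(tz, "/"), lz)
    return mesh
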