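"""1D Purkinje tree: bar-element FEM, Purkinje-muscle junctions (PMJs),
synthetic tree generation and coupled 1D/3D assembly.

The tree is a branched cable of 2-node bar elements with Lagrangian linear
interpolation; 3D shape-function gradients follow from the chain rule along
the segment direction cosines, and the volume Jacobian is segment length
times cross-sectional area. A PMJ connects a terminal Purkinje node to the
k myocardial nodes within a search radius through k bar elements of fixed
length that share the terminal's direction cosines and split the
cross-sectional area equally (A/k each), so current is conserved by
Kirchhoff's law without node-tying constraints.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .cells.kernel import PURKINJE_MULT, VENTRICULAR_MULT
from .fem import DEFAULT_BETA, DEFAULT_CM, SemidiscreteSystem
from .mesh import _HEX_EDGES, TAG_ENDO_LV, TAG_ENDO_RV, HexMesh

#: default cross-sectional radius (µm) and PMJ bar length (µm)
DEFAULT_RADIUS = 250.0
DEFAULT_L_PMJ = 200.0

#: default Purkinje diffusivity (µm²/ms): calibrate_purkinje_diffusivity
#: output for a 1D cable conduction velocity of 2 mm/ms with the Purkinje
#: surrogate (200 µm bars, default solver settings)
DEFAULT_D_PURKINJE = 9.75684e5

#: default PMJ bar diffusivity as a fraction of the Purkinje diffusivity
DEFAULT_D_PMJ_FRACTION = 1.0


@dataclass
class PurkinjeTree:
    """Branched 1D cable: nodes (µm), 2-node segments, AV-node root and a
    uniform cross-sectional radius."""

    nodes: np.ndarray            # (p, 3) µm
    segments: np.ndarray         # (s, 2) int
    root: int
    radius: float = DEFAULT_RADIUS
    terminals: np.ndarray = None  # (t,) int node ids
    seed: int | None = None      # generation seed (metadata)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.segments = np.asarray(self.segments, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("tree nodes must be (p, 3)")
        if self.segments.ndim != 2 or self.segments.shape[1] != 2:
            raise ValueError("tree segments must be (s, 2)")
        if not self.radius > 0:
            raise ValueError("cross-sectional radius must be positive")
        p, s = len(self.nodes), len(self.segments)
        if not 0 <= self.root < p:
            raise ValueError("root node id out of range")
        if s != p - 1:
            raise ValueError("tree must be acyclic and connected "
                             f"(expected {p - 1} segments, got {s})")
        # connectivity check by union-find
        parent = list(range(p))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b in self.segments:
            ra, rb = find(int(a)), find(int(b))
            if ra == rb:
                raise ValueError("tree contains a cycle")
            parent[ra] = rb
        if len({find(i) for i in range(p)}) != 1:
            raise ValueError("tree is not connected")
        if np.any(self.segment_lengths() <= 0):
            raise ValueError("zero-length segment")
        if self.terminals is None:
            deg = np.zeros(p, dtype=int)
            np.add.at(deg, self.segments.ravel(), 1)
            term = np.nonzero((deg == 1) & (np.arange(p) != self.root))[0]
            self.terminals = term
        else:
            self.terminals = np.asarray(self.terminals, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def area(self) -> float:
        """Cross-sectional area A = pi r^2 (µm²)."""
        return float(np.pi * self.radius ** 2)

    def segment_lengths(self) -> np.ndarray:
        d = self.nodes[self.segments[:, 1]] - self.nodes[self.segments[:, 0]]
        return np.linalg.norm(d, axis=1)

    def direction_cosines(self) -> np.ndarray:
        """Unit tangent per segment."""
        d = self.nodes[self.segments[:, 1]] - self.nodes[self.segments[:, 0]]
        return d / np.linalg.norm(d, axis=1, keepdims=True)


@dataclass
class PMJ:
    """One Purkinje-muscle junction: a terminal fanned out to k myocardial
    nodes through equal-area bar elements."""

    terminal: int                # tree node id
    myo_nodes: np.ndarray        # (k,) mesh node ids
    branch_area: float           # A/k (µm²) per branch
    length: float                # fixed bar length L_pmj (µm)
    direction: np.ndarray        # (3,) shared direction cosines
    fallback: bool = False       # True if nearest-node fallback was used

    def __post_init__(self) -> None:
        self.myo_nodes = np.asarray(self.myo_nodes, dtype=np.int64)
        self.direction = np.asarray(self.direction, dtype=float)
        if len(self.myo_nodes) == 0:
            raise ValueError("PMJ needs at least one myocardial branch")
        if not (self.branch_area > 0 and self.length > 0):
            raise ValueError("PMJ areas and length must be positive")

    @property
    def total_area(self) -> float:
        return self.branch_area * len(self.myo_nodes)


def bar_shape_gradients(x0, x1, direction=None):
    """3D shape-function gradients of a 2-node bar and its length.

    grad N1 = -a / L, grad N2 = +a / L with ``a`` the unit direction
    cosines (computed from the endpoints unless given) and L the segment
    length. The volume Jacobian of the element is L times the
    cross-sectional area (times the quadrature weight).
    """
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    d = x1 - x0
    length = float(np.linalg.norm(d))
    if length <= 0:
        raise ValueError("zero-length segment")
    a = d / length if direction is None else np.asarray(direction, float)
    grads = np.vstack([-a / length, a / length])
    return grads, length


def bar_stiffness(length: float, area: float, diffusivity: float) -> np.ndarray:
    """Element conductivity matrix of a bar: (d A / L) [[1,-1],[-1,1]]."""
    if length <= 0:
        raise ValueError("zero-length segment")
    k = diffusivity * area / length
    return k * np.array([[1.0, -1.0], [-1.0, 1.0]])


def _bar_mass(length: float, area: float) -> np.ndarray:
    """Consistent mass of a 2-node bar: (A L / 6) [[2,1],[1,2]]."""
    return area * length / 6.0 * np.array([[2.0, 1.0], [1.0, 2.0]])


# ---------------------------------------------------------------------------
# synthetic tree generation
# ---------------------------------------------------------------------------

def _surface_graph(mesh: HexMesh, tag: str):
    """Adjacency (sparse, edge lengths) over nodes carrying ``tag``."""
    on = mesh.surface_tags == tag
    ids = np.nonzero(on)[0]
    if len(ids) == 0:
        raise ValueError(f"no nodes tagged {tag!r}")
    pairs = mesh.elements[:, _HEX_EDGES].reshape(-1, 2)
    keep = on[pairs[:, 0]] & on[pairs[:, 1]]
    pairs = np.unique(np.sort(pairs[keep], axis=1), axis=0)
    lengths = np.linalg.norm(mesh.nodes[pairs[:, 0]] - mesh.nodes[pairs[:, 1]],
                             axis=1)
    adj: dict[int, list] = {int(i): [] for i in ids}
    for (a, b), w in zip(pairs, lengths):
        adj[int(a)].append((int(b), float(w)))
        adj[int(b)].append((int(a), float(w)))
    return ids, adj


def _surface_path(adj, start, targets, blocked):
    """Shortest path along the surface graph from ``start`` to the nearest
    node in ``targets`` avoiding ``blocked`` interiors. Returns the node
    list start..target or None."""
    dist = {start: 0.0}
    prev = {}
    heap = [(0.0, start)]
    seen = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in seen:
            continue
        seen.add(u)
        if u in targets:
            path = [u]
            while path[-1] != start:
                path.append(prev[path[-1]])
            return path[::-1]
        for v, w in adj.get(u, ()):
            if v in blocked and v not in targets:
                continue
            nd = d + w
            if nd < dist.get(v, np.inf):
                dist[v] = nd
                prev[v] = u
                heapq.heappush(heap, (nd, v))
    return None


def generate_synthetic_tree(mesh: HexMesh, n_pmj: int, seed: int = 0,
                            radius: float = DEFAULT_RADIUS,
                            min_separation: float = 0.0) -> PurkinjeTree:
    """Seeded synthetic Purkinje tree on the endocardial surfaces.

    The root (AV-node site) sits at a septal-base location and bifurcates
    into LV and RV bundle branches; terminal sites are sampled over both
    endocardial surfaces (proportional to surface size) and connected to
    the growing tree by shortest surface paths, producing a branched,
    surface-constrained arborization. Deterministic given ``seed``; the
    terminal count equals ``n_pmj`` exactly. ``min_separation`` (µm)
    enforces a minimum pairwise distance between terminal sites (keep it
    above twice the PMJ search radius for non-overlapping junction
    footprints).
    """
    if n_pmj < 2:
        raise ValueError("target PMJ count must be at least 2")
    rng = np.random.default_rng(seed)
    sides = {}
    for tag in (TAG_ENDO_LV, TAG_ENDO_RV):
        ids, adj = _surface_graph(mesh, tag)
        sides[tag] = (ids, adj)
    n_lv_nodes = len(sides[TAG_ENDO_LV][0])
    n_rv_nodes = len(sides[TAG_ENDO_RV][0])
    n_lv = max(1, int(round(n_pmj * n_lv_nodes / (n_lv_nodes + n_rv_nodes))))
    n_lv = min(n_lv, n_pmj - 1)
    counts = {TAG_ENDO_LV: n_lv, TAG_ENDO_RV: n_pmj - n_lv}

    zmax = mesh.nodes[:, 2].max()
    tree_nodes = []
    tree_segments = []
    terminals = []

    def add_node(xyz):
        tree_nodes.append(np.asarray(xyz, dtype=float))
        return len(tree_nodes) - 1

    # entry (bundle-branch) sites: the most basal septal node of each side
    entries = {}
    for tag, (ids, _) in sides.items():
        pts = mesh.nodes[ids]
        score = pts[:, 2] - np.abs(pts[:, 0])      # basal and near x = 0
        entries[tag] = int(ids[np.argmax(score)])

    root_xyz = 0.5 * (mesh.nodes[entries[TAG_ENDO_LV]]
                      + mesh.nodes[entries[TAG_ENDO_RV]])
    root_xyz[2] = min(zmax, root_xyz[2] + 2 * DEFAULT_L_PMJ)
    root = add_node(root_xyz)

    for tag in (TAG_ENDO_LV, TAG_ENDO_RV):
        ids, adj = sides[tag]
        entry_mesh = entries[tag]
        if counts[tag] > len(ids) - 1:
            raise ValueError(
                f"{tag} surface too small for {counts[tag]} terminals")
        entry_tree = add_node(mesh.nodes[entry_mesh])
        tree_segments.append((root, entry_tree))
        mesh2tree = {entry_mesh: entry_tree}
        candidates = ids[ids != entry_mesh]
        if min_separation <= 0:
            picks = rng.choice(candidates, size=counts[tag], replace=False)
        else:
            shuffled = rng.permutation(candidates)
            picks_list: list[int] = []
            kept = np.empty((0, 3))
            for c in shuffled:
                xyz = mesh.nodes[c]
                if len(picks_list) and np.min(
                        np.linalg.norm(kept - xyz, axis=1)) < min_separation:
                    continue
                picks_list.append(int(c))
                kept = np.vstack([kept, xyz])
                if len(picks_list) == counts[tag]:
                    break
            if len(picks_list) < counts[tag]:
                raise ValueError(
                    f"{tag} surface too small for {counts[tag]} terminals "
                    f"at min_separation {min_separation}")
            picks = np.array(picks_list)
        # connect near-to-far so later paths can merge into earlier branches
        entry_xyz = mesh.nodes[entry_mesh]
        order = np.argsort(np.linalg.norm(mesh.nodes[picks] - entry_xyz,
                                          axis=1))
        chosen = set(int(p) for p in picks)
        for t_mesh in (int(p) for p in picks[order]):
            if t_mesh in mesh2tree:        # already absorbed into the tree
                terminals.append(mesh2tree[t_mesh])
                continue
            path = _surface_path(adj, t_mesh, set(mesh2tree), chosen)
            if path is None:
                raise ValueError(
                    f"surface component of node {t_mesh} not reachable; "
                    f"{tag} surface too fragmented for the target count")
            # path runs terminal -> ... -> existing tree node
            prev_tree = mesh2tree[path[-1]]
            for m in path[-2::-1]:
                nid = add_node(mesh.nodes[m])
                mesh2tree[m] = nid
                tree_segments.append((prev_tree, nid))
                prev_tree = nid
            terminals.append(mesh2tree[t_mesh])

    tree = PurkinjeTree(np.array(tree_nodes), np.array(tree_segments),
                        root=root, radius=radius,
                        terminals=np.array(sorted(set(terminals))),
                        seed=seed)
    if len(tree.terminals) != n_pmj:
        raise ValueError(
            f"tree generation produced {len(tree.terminals)} terminals "
            f"instead of {n_pmj}; increase surface resolution")
    return tree


# ---------------------------------------------------------------------------
# PMJ attachment and coupled assembly
# ---------------------------------------------------------------------------

def attach_pmjs(tree: PurkinjeTree, mesh: HexMesh,
                search_radius: float | None = None,
                l_pmj: float = DEFAULT_L_PMJ) -> list[PMJ]:
    """PMJ elements for every tree terminal.

    Myocardial nodes within ``search_radius`` (default: the tree
    cross-sectional radius) of the terminal become branches with equal area
    fractions A/k; a terminal with no in-radius node falls back to the
    single nearest endocardial node (flagged).
    """
    from scipy.spatial import cKDTree

    if search_radius is None:
        search_radius = tree.radius
    if search_radius < 0:
        raise ValueError("search radius must be non-negative")
    kd_all = cKDTree(mesh.nodes)
    endo = np.nonzero(np.isin(mesh.surface_tags,
                              (TAG_ENDO_LV, TAG_ENDO_RV)))[0]
    kd_endo = cKDTree(mesh.nodes[endo]) if len(endo) else kd_all

    # terminal direction cosines: tangent of the segment ending there
    seg_dir = tree.direction_cosines()
    term_dir = {}
    for s, (a, b) in enumerate(tree.segments):
        term_dir[int(b)] = seg_dir[s]
        term_dir[int(a)] = -seg_dir[s]

    out = []
    for t in tree.terminals:
        p = tree.nodes[t]
        near = kd_all.query_ball_point(p, search_radius) if search_radius > 0 \
            else []
        fallback = len(near) == 0
        if fallback:
            if len(endo):
                near = [int(endo[kd_endo.query(p)[1]])]
            else:
                near = [int(kd_all.query(p)[1])]
        k = len(near)
        out.append(PMJ(int(t), np.array(sorted(near)), tree.area / k, l_pmj,
                       term_dir.get(int(t), np.array([0.0, 0.0, 1.0])),
                       fallback=fallback))
    return out


@dataclass
class CoupledSystem:
    """Myocardial + Purkinje semidiscrete system with per-node model
    binding. Global DOF order: mesh nodes first, then tree nodes."""

    system: SemidiscreteSystem
    n_myo: int
    tree: PurkinjeTree
    pmjs: list
    mult: np.ndarray             # (n_total, 6) per-node multipliers

    @property
    def n_total(self) -> int:
        return self.system.n_nodes

    def tree_dof(self, tree_node: int) -> int:
        return self.n_myo + int(tree_node)


def assemble_coupled(mesh: HexMesh, sigma, tree: PurkinjeTree, pmjs,
                     d_purkinje: float = DEFAULT_D_PURKINJE,
                     d_pmj: float | None = None,
                     mult_myo: np.ndarray | None = None,
                     cm: float = DEFAULT_CM,
                     beta: float = DEFAULT_BETA) -> CoupledSystem:
    """Single global operator set for the coupled 1D/3D system.

    3D blocks come from the standard hexahedral assembly, 1D blocks from
    bar elements along the tree, and PMJ blocks from bar elements of split
    area A/k between each terminal and its myocardial nodes. Purkinje DOFs
    are bound to the Purkinje surrogate, myocardial DOFs to the supplied
    regional multipliers (ventricular default).

    ``d_pmj`` is the junctional diffusivity of the PMJ bars (default:
    ``d_purkinje``). Lowering it makes the junction resistive, which
    lengthens the PMJ transmission delay; capture of the 3D tissue
    requires mesh edges of roughly 250 µm or finer (the junction current
    is bounded by the cable cross-section and cannot charge the liminal
    volume of a coarser grid).
    """
    from .fem import assemble

    if d_pmj is None:
        d_pmj = DEFAULT_D_PMJ_FRACTION * d_purkinje
    base = assemble(mesh, sigma, cm=cm, beta=beta)
    n_myo = mesh.n_nodes
    n_tot = n_myo + tree.n_nodes
    scale = cm * beta

    rows, cols, kv, mv = [], [], [], []

    def add_bar(i, j, length, area, diff):
        ke = bar_stiffness(length, area, diff)
        me = _bar_mass(length, area)
        for a, gi in enumerate((i, j)):
            for b, gj in enumerate((i, j)):
                rows.append(gi)
                cols.append(gj)
                kv.append(scale * ke[a, b])
                mv.append(me[a, b])

    lengths = tree.segment_lengths()
    for s, (a, b) in enumerate(tree.segments):
        add_bar(n_myo + int(a), n_myo + int(b), lengths[s], tree.area,
                d_purkinje)
    for pmj in pmjs:
        if np.any(pmj.myo_nodes >= n_myo) or pmj.terminal >= tree.n_nodes:
            raise ValueError("PMJ references unknown nodes")
        for m in pmj.myo_nodes:
            add_bar(n_myo + int(pmj.terminal), int(m), pmj.length,
                    pmj.branch_area, d_pmj)

    K1 = sp.coo_matrix((kv, (rows, cols)), shape=(n_tot, n_tot)).tocsr()
    M1 = sp.coo_matrix((mv, (rows, cols)), shape=(n_tot, n_tot)).tocsr()
    K = sp.block_diag([base.stiffness,
                       sp.csr_matrix((tree.n_nodes, tree.n_nodes))]).tocsr() \
        + K1
    M = sp.block_diag([base.mass,
                       sp.csr_matrix((tree.n_nodes, tree.n_nodes))]).tocsr() \
        + M1
    mass_lump = np.asarray(M.sum(axis=1)).ravel()
    system = SemidiscreteSystem(scale * mass_lump, K, M, mass_lump, cm, beta)

    if mult_myo is None:
        mult_myo = np.tile(VENTRICULAR_MULT, (n_myo, 1))
    mult = np.vstack([np.asarray(mult_myo, dtype=float),
                      np.tile(PURKINJE_MULT, (tree.n_nodes, 1))])
    return CoupledSystem(system, n_myo, tree, pmjs, mult)


# ---------------------------------------------------------------------------
# 1D cable calibration
# ---------------------------------------------------------------------------

def straight_cable(length: float, edge: float,
                   radius: float = DEFAULT_RADIUS) -> PurkinjeTree:
    """Straight 1D cable along x (calibration fixture)."""
    n = int(round(length / edge)) + 1
    nodes = np.zeros((n, 3))
    nodes[:, 0] = np.linspace(0.0, length, n)
    segs = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    return PurkinjeTree(nodes, segs, root=0, radius=radius)


def cable_cv(d_purkinje: float, length: float = 20000.0, edge: float = 200.0,
             config=None) -> float:
    """Conduction velocity (µm/ms) of the Purkinje surrogate on a straight
    1D cable paced at one end."""
    from .fem import (SolverConfig, Stepper, TissueStimulus, initial_state,
                      measure_cv, run_simulation)

    tree = straight_cable(length, edge)
    n = tree.n_nodes
    scale = DEFAULT_CM * DEFAULT_BETA
    rows, cols, kv, mv = [], [], [], []
    lengths = tree.segment_lengths()
    for s, (a, b) in enumerate(tree.segments):
        ke = bar_stiffness(lengths[s], tree.area, d_purkinje)
        me = _bar_mass(lengths[s], tree.area)
        for i, gi in enumerate((a, b)):
            for j, gj in enumerate((a, b)):
                rows.append(gi); cols.append(gj)
                kv.append(scale * ke[i, j]); mv.append(me[i, j])
    K = sp.coo_matrix((kv, (rows, cols)), shape=(n, n)).tocsr()
    M = sp.coo_matrix((mv, (rows, cols)), shape=(n, n)).tocsr()
    ml = np.asarray(M.sum(axis=1)).ravel()
    system = SemidiscreteSystem(scale * ml, K, M, ml, DEFAULT_CM, DEFAULT_BETA)
    mult = np.tile(PURKINJE_MULT, (n, 1))
    # stimulate a 1 mm end region: enough charge to ignite even when a high
    # diffusivity makes the electrotonic load large
    n_stim = max(3, int(round(1000.0 / edge)) + 1)
    stim = TissueStimulus(np.arange(n_stim), amplitude=80.0, duration=2.0)
    config = config or SolverConfig()
    cv_est = 2000.0 * np.sqrt(d_purkinje / 1.0e6)
    res = run_simulation(system, [stim], 1.5 * length / cv_est + 10.0,
                         config, mult=mult, store_series=False)
    return measure_cv(res.activation_times, tree.nodes,
                      (0.3 * length, 0, 0), (0.7 * length, 0, 0))


def calibrate_purkinje_diffusivity(target_cv: float = 2000.0,
                                   length: float = 20000.0,
                                   edge: float = 200.0,
                                   config=None, rel_tol: float = 0.01) -> float:
    """Purkinje diffusivity whose 1D cable CV matches ``target_cv``."""
    from scipy.optimize import brentq

    from .fem import CalibrationError

    cache = {}

    def cv_of(x):
        if x not in cache:
            cache[x] = cable_cv(float(np.exp(x)), length, edge, config)
        return cache[x]

    d0 = 1.0e6 * (target_cv / 2000.0) ** 2
    lo, hi = np.log(d0 / 8), np.log(d0 * 8)
    f = lambda x: cv_of(x) - target_cv
    if f(lo) * f(hi) > 0:
        raise CalibrationError(
            f"target CV {target_cv} outside achieved range "
            f"[{cv_of(lo):.1f}, {cv_of(hi):.1f}] um/ms")
    x = brentq(f, lo, hi, xtol=np.log(1 + rel_tol) / 2)
    return float(np.exp(x))
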