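"""Monodomain FEM: assembly on trilinear hexahedra and operator-splitting
time integration with ionic-current interpolation.

The semidiscrete system is

    C dV/dt = -K V - (C_m beta) M I_ion + stimulus

with C the row-sum lumped capacitance (C_m beta x mass), K the conductivity
(stiffness) operator assembled from grad(N)^T sigma grad(N), and M the
consistent mass operator retained for ionic-current interpolation: during
the reaction substep the nodal ionic current is mapped through M and divided
by the lumped mass before updating V. The diffusion substep is backward
Euler on the lumped system, (C + dt K) V+ = C V. The scheme uses lumped
capacitance for both substeps and the consistent mass only for the ionic
term.

Units: coordinates µm, time ms, voltage mV, currents µA/µF, conductivity in
diffusivity form µm²/ms scaled by C_m·beta (the scale cancels inside the
solver but keeps the reported operators dimensionally faithful).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .cells.backends import MahajanBackend

#: default tissue constants: membrane capacitance per area (µF/mm²) and
#: surface-to-volume ratio (1/mm). They enter C and K identically and cancel
#: in the update; exposed so either convention can be reported.
DEFAULT_CM = 0.01
DEFAULT_BETA = 140.0

_GAUSS = 1.0 / np.sqrt(3.0)


class AssemblyError(ValueError):
    pass


class SolverError(RuntimeError):
    pass


class DivergenceError(RuntimeError):
    """Simulation left the physical voltage range; carries the last valid
    checkpoint in ``checkpoint``."""

    def __init__(self, msg, checkpoint=None):
        super().__init__(msg)
        self.checkpoint = checkpoint


def _shape_gradients():
    """Reference shape-function values and gradients at the 2x2x2 Gauss
    points. Returns (n_vals (8 gp, 8 nodes), d_vals (8 gp, 8 nodes, 3))."""
    from .mesh import _HEX_OFFSETS

    signs = 2.0 * _HEX_OFFSETS - 1.0          # (8, 3) in {-1, +1}
    gps = _GAUSS * signs                      # reuse corner pattern for gps
    n_vals = np.empty((8, 8))
    d_vals = np.empty((8, 8, 3))
    for g, xi in enumerate(gps):
        for i, s in enumerate(signs):
            f = 1.0 + s * xi                  # (3,)
            n_vals[g, i] = 0.125 * f.prod()
            for a in range(3):
                d_vals[g, i, a] = 0.125 * s[a] * f[(a + 1) % 3] * f[(a + 2) % 3]
    return n_vals, d_vals


_N_VALS, _D_VALS = _shape_gradients()


@dataclass
class SemidiscreteSystem:
    """Assembled operators of the monodomain FEM system."""

    c_lump: np.ndarray           # (n,) lumped capacitance, C_m*beta scaled
    stiffness: sp.csr_matrix     # K, sigma scaled by C_m*beta
    mass: sp.csr_matrix          # consistent mass (unscaled volume integrals)
    mass_lump: np.ndarray        # (n,) row sums of mass
    cm: float
    beta: float

    @property
    def n_nodes(self) -> int:
        return len(self.c_lump)


def assemble(mesh, sigma, cm: float = DEFAULT_CM,
             beta: float = DEFAULT_BETA) -> SemidiscreteSystem:
    """Assemble lumped capacitance, consistent mass and stiffness operators.

    ``sigma`` is a ConductivityField (one SPD tensor per element, µm²/ms
    diffusivity form). 2x2x2 Gauss quadrature, exact for trilinear mass
    terms on parallelepipeds.
    """
    tensors = sigma.tensors
    if len(tensors) != mesh.n_elements:
        raise AssemblyError("one conductivity tensor per element required")
    bad = np.nonzero(np.linalg.eigvalsh(tensors)[:, 0] <= 0)[0]
    if len(bad):
        raise AssemblyError(
            f"conductivity not positive-definite on elements {bad[:5].tolist()}")

    X = mesh.nodes[mesh.elements]                       # (m, 8, 3)
    m = mesh.n_elements
    ke = np.zeros((m, 8, 8))
    me = np.zeros((m, 8, 8))
    scale = cm * beta
    for g in range(8):
        dN = _D_VALS[g]                                 # (8, 3)
        J = np.einsum("mib,ia->mba", X, dN)             # dx_b/dxi_a
        detJ = np.abs(np.linalg.det(J))
        Jinv = np.linalg.inv(J)                         # dxi_a/dx_b
        G = np.einsum("ia,mab->mib", dN, Jinv)          # grad_x N_i
        sG = np.einsum("mbc,mic->mib", tensors, G)
        ke += detJ[:, None, None] * np.einsum("mib,mjb->mij", G, sG)
        N = _N_VALS[g]
        me += detJ[:, None, None] * np.outer(N, N)[None, :, :]

    rows = np.repeat(mesh.elements, 8, axis=1).ravel()
    cols = np.tile(mesh.elements, (1, 8)).ravel()
    n = mesh.n_nodes
    K = sp.coo_matrix((scale * ke.ravel(), (rows, cols)),
                      shape=(n, n)).tocsr()
    M = sp.coo_matrix((me.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    mass_lump = np.asarray(M.sum(axis=1)).ravel()
    return SemidiscreteSystem(scale * mass_lump, K, M, mass_lump, cm, beta)


@dataclass(frozen=True)
class SolverConfig:
    """Time-integration parameters."""

    dt_pde: float = 0.1          # diffusion step (ms)
    dt_ode: float = 0.02         # reaction substep (ms)
    splitting: str = "godunov"   # godunov | strang
    theta: float = 1.0           # diffusion theta-method (1 = backward Euler)
    lin_tol: float = 1e-8        # relative tolerance of the iterative solve
    linear_solver: str = "auto"  # auto | direct | cg
    output_every: float = 1.0    # ms between stored frames
    checkpoint_every: float = 100.0  # ms between checkpoints

    def __post_init__(self) -> None:
        if not (self.dt_ode > 0 and self.dt_pde > 0):
            raise ValueError("time steps must be positive")
        if self.dt_ode > self.dt_pde + 1e-12:
            raise ValueError("dt_ode must not exceed dt_pde")
        if self.splitting not in ("godunov", "strang"):
            raise ValueError("splitting must be 'godunov' or 'strang'")
        if not self.lin_tol > 0:
            raise ValueError("linear tolerance must be positive")
        if self.linear_solver not in ("auto", "direct", "cg"):
            raise ValueError("linear_solver must be auto, direct or cg")
        if not 0.5 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0.5, 1]")


@dataclass(frozen=True)
class TissueStimulus:
    """Current injection on a node set (µA/µF, depolarizing positive),
    optionally periodic."""

    nodes: np.ndarray
    amplitude: float = 40.0
    onset: float = 0.0
    duration: float = 1.0
    cycle_length: float | None = None
    n_beats: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes",
                           np.asarray(self.nodes, dtype=np.int64))
        if not self.duration > 0:
            raise ValueError("stimulus duration must be > 0")
        if self.cycle_length is not None and self.cycle_length <= self.duration:
            raise ValueError("cycle length must exceed stimulus duration")
        if len(self.nodes) == 0:
            raise ValueError("stimulus needs at least one node")

    def active(self, t: float) -> bool:
        if self.cycle_length is None:
            return self.onset <= t < self.onset + self.duration
        k = np.floor((t - self.onset) / self.cycle_length)
        if k < 0 or k >= self.n_beats:
            return False
        phase = t - self.onset - k * self.cycle_length
        return phase < self.duration


@dataclass
class SimulationState:
    """Nodal voltages, per-node cell states and current time."""

    V: np.ndarray                # (n,) mV
    Q: np.ndarray                # (n, n_states)
    t: float = 0.0

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.V)) and np.all(np.isfinite(self.Q))):
            raise ValueError("non-finite entries in simulation state")
        if len(self.V) != len(self.Q):
            raise ValueError("V and Q node counts differ")

    def copy(self) -> "SimulationState":
        return SimulationState(self.V.copy(), self.Q.copy(), self.t)


def initial_state(n_nodes: int, backend=None) -> SimulationState:
    backend = backend or MahajanBackend()
    V = np.full(n_nodes, backend.rest_v)
    Q = np.tile(backend.rest_q(), (n_nodes, 1))
    return SimulationState(V, Q)


class _DiffusionSolver:
    """Theta-method solve (C + theta dt K) V+ = (C - (1-theta) dt K) V with
    cached factorization (direct) or Jacobi-preconditioned CG. theta = 1 is
    backward Euler, theta = 0.5 Crank-Nicolson."""

    def __init__(self, system: SemidiscreteSystem, dt: float,
                 config: SolverConfig):
        theta = config.theta
        self.C = system.c_lump
        A = sp.diags(system.c_lump) + theta * dt * system.stiffness
        self.B = (sp.diags(system.c_lump)
                  - (1.0 - theta) * dt * system.stiffness).tocsr() \
            if theta < 1.0 else None
        self.A = A.tocsr()
        mode = config.linear_solver
        if mode == "auto":
            mode = "direct" if system.n_nodes <= 400_000 else "cg"
        self.mode = mode
        self.tol = config.lin_tol
        if mode == "direct":
            self.lu = spla.splu(self.A.tocsc())
        else:
            self.pre = sp.diags(1.0 / self.A.diagonal())

    def solve(self, V: np.ndarray) -> np.ndarray:
        b = self.C * V if self.B is None else self.B @ V
        if self.mode == "direct":
            return self.lu.solve(b)
        x, info = spla.cg(self.A, b, x0=V, rtol=self.tol, maxiter=2000,
                          M=self.pre)
        if info != 0:
            res = np.linalg.norm(self.A @ x - b) / max(np.linalg.norm(b), 1e-30)
            raise SolverError(
                f"diffusion solve failed (cg info={info}, residual={res:.2e})")
        return x


class Stepper:
    """Operator-splitting integrator bound to one assembled system."""

    def __init__(self, system: SemidiscreteSystem, config: SolverConfig,
                 backend=None, mult: np.ndarray | None = None,
                 stimuli=(), consistent_ionic: bool = True):
        from .cells.kernel import VENTRICULAR_MULT

        self.system = system
        self.config = config
        self.backend = backend or MahajanBackend()
        n = system.n_nodes
        if mult is None:
            mult = np.tile(VENTRICULAR_MULT, (n, 1))
        self.mult = np.ascontiguousarray(mult, dtype=float)
        if len(self.mult) != n:
            raise ValueError("one multiplier row per node required")
        self.stimuli = list(stimuli)
        self.consistent_ionic = consistent_ionic
        self._iion = np.empty(n)
        self._solvers: dict[float, _DiffusionSolver] = {}
        self._n_sub = max(1, int(round(config.dt_pde / config.dt_ode)))
        self._dt_ode = config.dt_pde / self._n_sub

    def _solver(self, dt: float) -> _DiffusionSolver:
        if dt not in self._solvers:
            self._solvers[dt] = _DiffusionSolver(self.system, dt, self.config)
        return self._solvers[dt]

    def _reaction(self, state: SimulationState, dt_total: float) -> None:
        M = self.system.mass
        ml = self.system.mass_lump
        for _ in range(self._n_sub if dt_total == self.config.dt_pde
                       else max(1, int(round(dt_total / self._dt_ode)))):
            dt = self._dt_ode
            self.backend.step(state.V, state.Q, dt, self.mult, self._iion)
            if self.consistent_ionic:
                rhs = (M @ self._iion) / ml
            else:
                rhs = self._iion
            state.V -= dt * rhs
            for stim in self.stimuli:
                if stim.active(state.t):
                    state.V[stim.nodes] += dt * stim.amplitude
            state.t += dt

    def step(self, state: SimulationState) -> SimulationState:
        """Advance by one dt_pde (in place; also returns the state)."""
        dt = self.config.dt_pde
        if self.config.splitting == "godunov":
            self._reaction(state, dt)
            state.V = self._solver(dt).solve(state.V)
        else:
            state.V = self._solver(dt / 2).solve(state.V)
            self._reaction(state, dt)
            state.V = self._solver(dt / 2).solve(state.V)
        return state


@dataclass
class SimulationResult:
    """Decimated voltage series plus online activation times."""

    times: np.ndarray            # (n_frames,)
    V_series: np.ndarray         # (n_frames, n_nodes)
    final_state: SimulationState
    activation_times: np.ndarray  # (n_nodes,) first crossing, NaN if never
    checkpoints: list = field(default_factory=list)


def run_simulation(system: SemidiscreteSystem, stimuli, duration: float,
                   config: SolverConfig | None = None, backend=None,
                   mult: np.ndarray | None = None,
                   state: SimulationState | None = None,
                   activation_threshold: float = -40.0,
                   store_series: bool = True,
                   consistent_ionic: bool = True) -> SimulationResult:
    """Integrate the monodomain system for ``duration`` ms.

    Deterministic: identical inputs produce identical outputs. Aborts with
    DivergenceError (carrying the last checkpoint) if any |V| > 1000 mV.
    Activation times are tracked online as the first upward crossing of
    ``activation_threshold``, linearly interpolated within the PDE step.
    """
    config = config or SolverConfig()
    stepper = Stepper(system, config, backend=backend, mult=mult,
                      stimuli=stimuli, consistent_ionic=consistent_ionic)
    if state is None:
        state = initial_state(system.n_nodes, stepper.backend)
    n_steps = int(round(duration / config.dt_pde))
    out_stride = max(1, int(round(config.output_every / config.dt_pde)))
    ckpt_stride = max(1, int(round(config.checkpoint_every / config.dt_pde)))

    n = system.n_nodes
    act = np.full(n, np.nan)
    frames, times = [], []
    checkpoints = [state.copy()]
    if store_series:
        frames.append(state.V.copy())
        times.append(state.t)
    v_prev = state.V.copy()
    t_prev = state.t
    for k in range(1, n_steps + 1):
        stepper.step(state)
        if np.abs(state.V).max() > 1000.0 or not np.all(np.isfinite(state.V)):
            raise DivergenceError(
                f"simulation diverged at t={state.t:.3f} ms",
                checkpoint=checkpoints[-1])
        newly = np.isnan(act) & (v_prev < activation_threshold) \
            & (state.V >= activation_threshold)
        if newly.any():
            f = (activation_threshold - v_prev[newly]) \
                / (state.V[newly] - v_prev[newly])
            act[newly] = t_prev + f * (state.t - t_prev)
        v_prev[:] = state.V
        t_prev = state.t
        if store_series and k % out_stride == 0:
            frames.append(state.V.copy())
            times.append(state.t)
        if k % ckpt_stride == 0:
            checkpoints = [state.copy()]   # keep only the latest
    V_series = (np.array(frames) if store_series
                else np.empty((0, n)))
    return SimulationResult(np.array(times), V_series, state, act,
                            checkpoints)


class NotActivatedError(RuntimeError):
    pass


def measure_cv(activation_times: np.ndarray, coords: np.ndarray,
               probe_a, probe_b) -> float:
    """Conduction velocity between two probe points (distance units per ms).

    ``probe_a``/``probe_b`` are node indices or coordinate triples (nearest
    node is used). Both probes must be activated and must not share an
    activation time.
    """
    coords = np.asarray(coords, dtype=float)

    def resolve(p):
        if np.isscalar(p) or isinstance(p, (int, np.integer)):
            return int(p)
        d = np.linalg.norm(coords - np.asarray(p, float), axis=1)
        return int(np.argmin(d))

    ia, ib = resolve(probe_a), resolve(probe_b)
    ta, tb = activation_times[ia], activation_times[ib]
    if not (np.isfinite(ta) and np.isfinite(tb)):
        raise NotActivatedError("a probe point never activated")
    if ta == tb:
        raise NotActivatedError("probe points activated simultaneously")
    return float(np.linalg.norm(coords[ia] - coords[ib]) / abs(tb - ta))


def slab_cv(d_l: float, slab_extent, edge, config, backend=None,
            cv_probe_frac=(0.3, 0.7), duration=None) -> float:
    """Longitudinal CV (µm/ms) on a slab paced from the x=0 face."""
    from .mesh import build_slab_mesh
    from .tensors import axis_aligned_conductivity

    mesh = build_slab_mesh(slab_extent, edge)
    sigma = axis_aligned_conductivity(mesh.n_elements, d_l, fiber_axis=0)
    system = assemble(mesh, sigma)
    x = mesh.nodes[:, 0]
    # stimulate a 500 um-deep end region so ignition succeeds even under
    # strong diffusive loading at the top of the calibration bracket
    stim_nodes = np.nonzero(x < x.min() + 500.0 + 1e-6)[0]
    stim = TissueStimulus(stim_nodes, amplitude=60.0, duration=2.0)
    length = slab_extent[0]
    if duration is None:
        cv_est = 700.0 * np.sqrt(d_l / 1.0e5)   # cable-theory scaling guess
        duration = 1.5 * length / cv_est + 10.0
    cfg = replace(config, output_every=config.dt_pde) if config else SolverConfig()
    res = run_simulation(system, [stim], duration, cfg, backend=backend,
                         store_series=False)
    yz_mid = mesh.nodes[:, 1:].mean(axis=0)
    xa, xb = cv_probe_frac[0] * length, cv_probe_frac[1] * length
    pa = np.concatenate([[xa], yz_mid])
    pb = np.concatenate([[xb], yz_mid])
    return measure_cv(res.activation_times, mesh.nodes, pa, pb)


class CalibrationError(RuntimeError):
    pass


def calibrate_diffusivity(target_cv: float,
                          slab_extent=(10000.0, 600.0, 600.0),
                          edge: float = 200.0,
                          config: SolverConfig | None = None,
                          backend=None,
                          bracket_scale: float = 8.0,
                          rel_tol: float = 0.01) -> float:
    """Longitudinal diffusivity (µm²/ms) whose planar slab CV matches
    ``target_cv`` (µm/ms) within ``rel_tol``.

    Scalar root-finding on log(d_l); the initial guess uses the cable-theory
    scaling CV proportional to sqrt(d_l).
    """
    from scipy.optimize import brentq

    if not target_cv > 0:
        raise CalibrationError("target CV must be positive")
    config = config or SolverConfig()
    cache: dict[float, float] = {}

    def cv_of(log_d):
        if log_d not in cache:
            cache[log_d] = slab_cv(float(np.exp(log_d)), slab_extent, edge,
                                    config, backend)
        return cache[log_d]

    d0 = 1.0e5 * (target_cv / 700.0) ** 2     # sqrt scaling from a known point
    lo, hi = np.log(d0 / bracket_scale), np.log(d0 * bracket_scale)
    f = lambda x: cv_of(x) - target_cv
    try:
        f_lo, f_hi = f(lo), f(hi)
        if f_lo * f_hi > 0:
            raise CalibrationError(
                f"target CV {target_cv} outside achieved range "
                f"[{cv_of(lo):.1f}, {cv_of(hi):.1f}] um/ms")
        x = brentq(f, lo, hi, xtol=np.log(1 + rel_tol) / 2)
    except NotActivatedError as exc:
        raise CalibrationError(f"calibration slab failed to conduct: {exc}")
    d = float(np.exp(x))
    achieved = cv_of(x)
    if abs(achieved - target_cv) > rel_tol * target_cv:
        warnings.warn(f"diffusivity calibration achieved CV {achieved:.2f} "
                      f"vs target {target_cv}")
    return d

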