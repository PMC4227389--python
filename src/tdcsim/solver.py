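"""Operator-splitting time integration and the preconditioned linear solver.

Each global step of length ``dt`` is a Godunov fractional step:

(1) reaction: advance the FitzHugh-Nagumo ODEs nodewise over ``dt`` with
    Heun substeps of length ``dt_ode``, giving the partial solution
    ``v_tilde`` (the recovery variable w is frozen through step 2);
(2) diffusion: one implicit-Euler step of the coupled bidomain/volume-
    conductor PDEs, i.e. one solve of the symmetric block system with
    right-hand side built from ``v_tilde``.

The block system is solved with conjugate gradients, preconditioned by the
block-diagonal operator diag(~A^-1, ~C^-1) where each tilde-inverse is a
relaxed ILU(0) factorization (RILU: fill dropped outside the sparsity
pattern is lumped onto the diagonal, scaled by a relaxation factor omega).
Convergence is monitored on the relative residual ||r_k|| / ||r_0||.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve_triangular

from .assembly import BlockSystem, apply_tdcs_bcs, assemble_blocks, build_conductivity, build_rhs
from .cell_model import CellState, FHNParams, ode_substep_loop
from .mesh import ElectrodeKind, ElectrodePatch, SimplicialMesh
from .postprocess import ProbeTrace

__all__ = [
    "SolverConfig",
    "SimulationState",
    "SimulationResult",
    "StimulusDisc",
    "ProbeSpec",
    "PCGBreakdownError",
    "PCGConvergenceError",
    "pcg_solve",
    "rilu0",
    "RILUFactor",
    "build_block_preconditioner",
    "godunov_step",
    "run_simulation",
]


@dataclass(frozen=True)
class SolverConfig:
    """Time stepping, physics constants, and linear-solver controls.

    ``chi`` (membrane area per tissue volume, 1/m) and ``c_m`` (membrane
    capacitance, F/m^2) set the diffusion scaling ``dt / (chi * c_m)``.
    """

    dt_global: float = 1.0e-3     # s
    dt_ode: float = 0.5e-3        # s
    t_end: float = 0.100          # s
    chi: float = 1.26e5           # 1/m
    c_m: float = 1.0e-4           # F/m^2
    cg_rel_tol: float = 1.0e-8
    ilu_relaxation: float = 0.5   # omega
    max_cg_iters: int = 5000
    warm_start: bool = True

    def __post_init__(self) -> None:
        if self.dt_ode > self.dt_global:
            raise ValueError("dt_ode must not exceed dt_global")
        if min(self.dt_global, self.dt_ode, self.cg_rel_tol) <= 0:
            raise ValueError("time steps and tolerance must be positive")


@dataclass
class SimulationState:
    """Membrane state on brain nodes plus the global electric potential."""

    cell: CellState
    phi: np.ndarray
    t: float = 0.0
    step: int = 0

    def copy(self) -> "SimulationState":
        return SimulationState(self.cell.copy(), self.phi.copy(), self.t, self.step)


@dataclass(frozen=True)
class StimulusDisc:
    """Applied-current stimulus: uniform I_app inside a disc, over a window.

    ``amplitude`` is in V/s (it adds directly to dv/dt in the membrane
    model) and acts during ODE substeps whose start time lies in
    [t_on, t_off).
    """

    center: tuple[float, float]
    radius: float
    t_on: float
    t_off: float
    amplitude: float

    def node_mask(self, mesh: SimplicialMesh, node_subset: np.ndarray) -> np.ndarray:
        pts = mesh.nodes[node_subset]
        c = np.asarray(self.center)[: mesh.dim]
        return np.linalg.norm(pts - c, axis=1) <= self.radius


@dataclass(frozen=True)
class ProbeSpec:
    """A named observation point: quantity 'v' (brain) or 'phi' (anywhere)."""

    name: str
    location: tuple[float, float]
    quantity: str = "v"


# ---------------------------------------------------------------------------
# Relaxed ILU(0)
# ---------------------------------------------------------------------------


class ZeroPivotError(RuntimeError):
    """A pivot vanished during incomplete factorization."""


class RILUFactor:
    """Relaxed ILU(0) factorization usable as a preconditioner apply."""

    def __init__(self, L: sp.csr_matrix, U: sp.csr_matrix):
        self.L = L
        self.U = U

    def apply(self, b: np.ndarray) -> np.ndarray:
        y = spsolve_triangular(self.L, b, lower=True, unit_diagonal=True)
        return spsolve_triangular(self.U, y, lower=False)


def rilu0(A: sp.spmatrix, omega: float = 0.5, pivot_rel_floor: float = 1e-13) -> RILUFactor:
    """Relaxed ILU(0) of a sparse matrix.

    No fill outside the sparsity pattern of A is kept; each dropped fill
    value is instead subtracted from the row's diagonal scaled by ``omega``
    (omega = 0 gives plain ILU(0), omega = 1 the modified ILU that
    preserves row sums).  A pivot smaller in magnitude than
    ``pivot_rel_floor`` times the row's 1-norm is replaced by that norm —
    this keeps the factorization usable on singular pure-Neumann operators
    whose last pivot degenerates; an exactly zero row raises
    :class:`ZeroPivotError`.
    """
    A = sp.csr_matrix(A)
    A.sort_indices()
    n = A.shape[0]
    rows: list[dict[int, float]] = []
    indptr, indices, data = A.indptr, A.indices, A.data
    for i in range(n):
        rows.append(
            {int(c): float(v) for c, v in zip(indices[indptr[i]:indptr[i + 1]],
                                              data[indptr[i]:indptr[i + 1]])}
        )
    upper: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    diag = np.zeros(n)
    for i in range(n):
        row = rows[i]
        for k in sorted(c for c in row if c < i):
            lik = row[k] / diag[k]
            row[k] = lik
            for j, ukj in upper[k]:
                upd = lik * ukj
                if j in row:
                    row[j] -= upd
                else:
                    row[i] = row.get(i, 0.0) - omega * upd
        piv = row.get(i, 0.0)
        rownorm = sum(abs(v) for v in row.values())
        if rownorm == 0.0:
            raise ZeroPivotError(f"row {i} is entirely zero")
        if abs(piv) < pivot_rel_floor * rownorm:
            piv = rownorm
            row[i] = piv
        diag[i] = piv
        upper[i] = [(j, v) for j, v in row.items() if j > i]

    # pack L (unit lower) and U (upper incl diagonal) as CSR
    li, lj, lv = [], [], []
    ui, uj, uv = [], [], []
    for i in range(n):
        for j, v in rows[i].items():
            if j < i:
                li.append(i); lj.append(j); lv.append(v)
            else:
                ui.append(i); uj.append(j); uv.append(v)
        li.append(i); lj.append(i); lv.append(1.0)
    L = sp.csr_matrix((lv, (li, lj)), shape=(n, n))
    U = sp.csr_matrix((uv, (ui, uj)), shape=(n, n))
    return RILUFactor(L, U)


class _JacobiFactor:
    def __init__(self, A: sp.spmatrix):
        d = np.asarray(sp.csr_matrix(A).diagonal())
        d[d == 0.0] = 1.0
        self.dinv = 1.0 / d

    def apply(self, b: np.ndarray) -> np.ndarray:
        return self.dinv * b


class BlockPreconditioner:
    """Block-diagonal preconditioner diag(~A^-1, ~C^-1)."""

    def __init__(self, A_solver, C_solver, n_v: int):
        self.A_solver = A_solver
        self.C_solver = C_solver
        self.n_v = n_v

    def apply(self, r: np.ndarray) -> np.ndarray:
        out = np.empty_like(r)
        out[: self.n_v] = self.A_solver.apply(r[: self.n_v])
        out[self.n_v :] = self.C_solver.apply(r[self.n_v :])
        return out


def build_block_preconditioner(system: BlockSystem, omega: float = 0.5) -> BlockPreconditioner:
    """RILU(0) solves of the constrained A and C blocks, applied independently.

    If a block's incomplete factorization breaks down (zero pivot), that
    block falls back to diagonal (Jacobi) scaling with a logged warning.
    """
    solvers = []
    for name, block in (("A", system.A), ("C", system.constrained_C())):
        try:
            solvers.append(rilu0(block, omega))
        except ZeroPivotError as exc:
            warnings.warn(
                f"RILU(0) of block {name} broke down ({exc}); "
                "falling back to Jacobi for this block"
            )
            solvers.append(_JacobiFactor(block))
    return BlockPreconditioner(solvers[0], solvers[1], system.n_v)


# ---------------------------------------------------------------------------
# Preconditioned conjugate gradients
# ---------------------------------------------------------------------------


class PCGBreakdownError(RuntimeError):
    """The operator or preconditioner is not positive definite."""


class PCGConvergenceError(RuntimeError):
    """CG failed to reach the requested tolerance; carries the history."""

    def __init__(self, msg: str, residuals: list[float]):
        super().__init__(msg)
        self.residuals = residuals


@dataclass
class CGLog:
    iterations: int
    residuals: list[float] = field(default_factory=list)


def pcg_solve(
    K: sp.spmatrix,
    b: np.ndarray,
    preconditioner=None,
    rel_tol: float = 1e-8,
    max_iters: int = 5000,
    x0: np.ndarray | None = None,
    ref_norm: float | None = None,
) -> tuple[np.ndarray, CGLog]:
    """Preconditioned CG with a relative-residual monitor ||r_k||/||r_0||.

    ``preconditioner`` exposes ``.apply(r)``; None means identity.  With
    ``x0 = None`` the iteration starts from zero, so ||r_0|| = ||b||.
    When warm-starting from a nearly converged guess, ``ref_norm`` can pin
    the monitor's denominator to a fixed scale (e.g. ||b||) — otherwise a
    tiny initial residual would make the relative criterion unattainably
    strict.  Breakdown (negative curvature / indefinite preconditioner) is
    reported distinctly from running out of iterations.
    """
    b = np.asarray(b, dtype=float)
    x = np.zeros_like(b) if x0 is None else np.array(x0, dtype=float)
    apply_M = (lambda r: r) if preconditioner is None else preconditioner.apply
    r = b - K @ x if x.any() else b.copy()
    r0_norm = float(np.linalg.norm(r)) if ref_norm is None else float(ref_norm)
    log = CGLog(iterations=0, residuals=[float(np.linalg.norm(r))])
    if r0_norm == 0.0 or log.residuals[0] == 0.0 or log.residuals[0] <= rel_tol * r0_norm:
        return x, log
    z = apply_M(r)
    p = z.copy()
    rz = float(r @ z)
    if rz < 0:
        raise PCGBreakdownError("preconditioner is not positive definite")
    for k in range(1, max_iters + 1):
        q = K @ p
        pq = float(p @ q)
        if pq <= 0.0:
            raise PCGBreakdownError(
                f"non-positive curvature p'Kp = {pq:g} at iteration {k}"
            )
        alpha = rz / pq
        x += alpha * p
        r -= alpha * q
        rnorm = float(np.linalg.norm(r))
        log.residuals.append(rnorm)
        log.iterations = k
        if rnorm / r0_norm <= rel_tol:
            return x, log
        z = apply_M(r)
        rz_new = float(r @ z)
        if rz_new < 0:
            raise PCGBreakdownError("preconditioner is not positive definite")
        p = z + (rz_new / rz) * p
        rz = rz_new
    raise PCGConvergenceError(
        f"CG did not reach rel_tol={rel_tol:g} in {max_iters} iterations "
        f"(last relative residual {log.residuals[-1] / r0_norm:.3e})",
        log.residuals,
    )


# ---------------------------------------------------------------------------
# Godunov splitting
# ---------------------------------------------------------------------------


def _phi_gauge(system: BlockSystem, phi: np.ndarray) -> np.ndarray:
    """Remove the constant mode on pure-Neumann runs (zero-mean gauge)."""
    if len(system.dirichlet_nodes):
        return phi
    meas = system.mesh.element_measures()
    w = np.zeros(system.n_phi)
    np.add.at(w, system.mesh.elements.ravel(),
              np.repeat(meas / (system.mesh.dim + 1), system.mesh.dim + 1))
    return phi - float(w @ phi) / float(w.sum())


def godunov_step(
    state: SimulationState,
    system: BlockSystem,
    cell_params: FHNParams,
    config: SolverConfig,
    preconditioner: BlockPreconditioner | None = None,
    i_app=0.0,
) -> tuple[SimulationState, CGLog]:
    """One full splitting step: reaction substeps, then one implicit solve."""
    dt = config.dt_global
    partial = ode_substep_loop(state.cell, cell_params, i_app, dt, config.dt_ode)
    rhs = build_rhs(system, partial.v)
    x0 = ref = None
    if config.warm_start:
        x0 = np.concatenate([partial.v, state.phi])
        ref = float(np.linalg.norm(rhs))
    x, log = pcg_solve(
        system.full_matrix(),
        rhs,
        preconditioner,
        rel_tol=config.cg_rel_tol,
        max_iters=config.max_cg_iters,
        x0=x0,
        ref_norm=ref,
    )
    v_new = x[: system.n_v]
    phi_new = _phi_gauge(system, x[system.n_v :])
    cell = CellState(v=v_new, w=partial.w, t=state.t + dt)
    return SimulationState(cell=cell, phi=phi_new, t=state.t + dt, step=state.step + 1), log


@dataclass
class SimulationResult:
    """Final state plus everything recorded along the way."""

    state: SimulationState
    traces: dict[str, ProbeTrace]
    snapshots: dict[float, dict[str, np.ndarray]]
    cg_iterations: list[int]
    system: BlockSystem


def _resolve_probe(
    probe: ProbeSpec, mesh: SimplicialMesh, brain_nodes: np.ndarray
) -> tuple[int, float, np.ndarray]:
    """Snap a probe to the nearest admissible node; returns (dof, dist, xy)."""
    loc = np.asarray(probe.location, dtype=float)[: mesh.dim]
    if probe.quantity == "v":
        cand = brain_nodes
    elif probe.quantity == "phi":
        cand = np.arange(mesh.n_nodes)
    else:
        raise ValueError(f"unknown probe quantity {probe.quantity!r}")
    d = np.linalg.norm(mesh.nodes[cand] - loc, axis=1)
    k = int(np.argmin(d))
    node = int(cand[k])
    if probe.quantity == "v":
        dof = int(np.searchsorted(brain_nodes, node))
    else:
        dof = node
    return dof, float(d[k]), mesh.nodes[node]


def run_simulation(
    mesh: SimplicialMesh,
    electrodes: list[ElectrodePatch] | None,
    cell_params: FHNParams | None = None,
    config: SolverConfig | None = None,
    probes: list[ProbeSpec] | None = None,
    stimulus: StimulusDisc | None = None,
    conductivity=None,
    snapshot_times: tuple[float, ...] = (),
) -> SimulationResult:
    """Run the multiscale model: assemble once, then march Godunov steps.

    Initial conditions are rest: v = v_rest on brain nodes, w = 0, Phi = 0.
    Probe traces are recorded at every global step (including t = 0) and
    field snapshots at the requested times (matched to the nearest step).
    """
    cell_params = cell_params or FHNParams()
    config = config or SolverConfig()
    probes = probes or []
    if conductivity is None:
        conductivity = build_conductivity(mesh)
    system = assemble_blocks(mesh, conductivity, config.chi, config.c_m, config.dt_global)
    anode = cathode = None
    for e in electrodes or []:
        if e.kind is ElectrodeKind.ANODE:
            anode = e
        else:
            cathode = e
    if anode is not None or cathode is not None:
        apply_tdcs_bcs(system, anode, cathode)
    precond = build_block_preconditioner(system, config.ilu_relaxation)

    brain_nodes = system.brain_nodes
    n_v = system.n_v
    state = SimulationState(
        cell=CellState(
            v=np.full(n_v, cell_params.v_rest), w=np.zeros(n_v), t=0.0
        ),
        phi=np.zeros(system.n_phi),
    )

    resolved = []
    for pr in probes:
        dof, dist, snapped = _resolve_probe(pr, mesh, brain_nodes)
        resolved.append((pr, dof, dist, snapped))

    i_app = 0.0
    if stimulus is not None:
        mask = stimulus.node_mask(mesh, brain_nodes).astype(float)
        stim = stimulus

        def i_app(t, _mask=mask, _s=stim):  # noqa: E731 - substep-time source
            return _s.amplitude * _mask if _s.t_on <= t < _s.t_off else 0.0

    n_steps = int(round(config.t_end / config.dt_global))
    times = [0.0]
    samples = {pr.name: [_sample(state, dof, pr)] for pr, dof, _, _ in resolved}
    snapshots: dict[float, dict[str, np.ndarray]] = {}
    snap_steps = {int(round(ts / config.dt_global)): ts for ts in snapshot_times}
    if 0 in snap_steps:
        snapshots[snap_steps[0]] = _snapshot(state)
    cg_iters: list[int] = []

    for _ in range(n_steps):
        state, log = godunov_step(state, system, cell_params, config, precond, i_app)
        cg_iters.append(log.iterations)
        times.append(state.t)
        for pr, dof, _, _ in resolved:
            samples[pr.name].append(_sample(state, dof, pr))
        if state.step in snap_steps:
            snapshots[snap_steps[state.step]] = _snapshot(state)
        if not (np.all(np.isfinite(state.cell.v)) and np.all(np.isfinite(state.phi))):
            raise FloatingPointError(f"non-finite solution at step {state.step}")

    traces = {
        pr.name: ProbeTrace(
            name=pr.name,
            location=tuple(snapped),
            quantity=pr.quantity,
            times=np.asarray(times),
            values=np.asarray(samples[pr.name]),
            snap_distance=dist,
        )
        for pr, dof, dist, snapped in resolved
    }
    return SimulationResult(
        state=state, traces=traces, snapshots=snapshots,
        cg_iterations=cg_iters, system=system,
    )


def _sample(state: SimulationState, dof: int, probe: ProbeSpec) -> float:
    return float(state.cell.v[dof] if probe.quantity == "v" else state.phi[dof])


def _snapshot(state: SimulationState) -> dict[str, np.ndarray]:
    return {"v": state.cell.v.copy(), "w": state.cell.w.copy(), "phi": state.phi.copy()}
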