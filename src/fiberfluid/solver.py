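"""Incremental quasi-static solution of the fiber–fluid system.

Loads are applied in ``n_steps`` equal increments.  At every increment the
right-hand side is rebuilt on the *current* (deformed) geometry — updated
vertex areas S_i and vertical drops h_i — and one linear solve yields the
incremental displacements and pressure variation, which are added to the
running state.

Two modes:

* ``linear_reuse`` — the matrix A is assembled once from the reference
  configuration and its LU factorization is reused for every increment
  (and for decompression).  This is the fast path for linear materials.
* ``nonlinear_refactor`` — A is reassembled and refactorized each increment
  from the current geometry, with Y_ij optionally supplied by a stiffness
  rule evaluated on the previous increment's pair displacements.

Because the right-hand side is discretized along the loading path, a full
load–unload cycle does not return exactly to the start; the residual shrinks
like 1/n with the number of increments (see :mod:`fiberfluid.metrics`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .assembly import LinearSystem, LoadCase, MaterialParams, assemble_matrix, assemble_rhs
from .fibers import FiberSet, build_fibers, cull_concave_fibers
from .geometry import surface_geometry
from .mesh import TriangleMesh

__all__ = [
    "SolverError",
    "SolverOptions",
    "StepRecord",
    "DeformationState",
    "solve_system",
    "run_quasistatic",
    "decompress",
    "compress_decompress_cycle",
]


class SolverError(RuntimeError):
    """Raised when the linear solve fails or produces invalid results."""


@dataclass
class SolverOptions:
    mode: str = "linear_reuse"  # or "nonlinear_refactor"
    n_steps: int = 10
    volume_residual_tolerance: float = 1e-8

    def check(self) -> None:
        if self.mode not in ("linear_reuse", "nonlinear_refactor"):
            raise ValueError(f"unknown solver mode {self.mode!r}")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass
class StepRecord:
    step: int
    load_fraction: float
    pressure_increment: float
    max_displacement: float
    volume_residual: float


@dataclass
class DeformationState:
    """Positions, cumulative displacements and pressure after a run."""

    reference: TriangleMesh
    positions: np.ndarray
    pressure_variation: float
    step_index: int
    history: list[StepRecord] = field(default_factory=list)

    @property
    def cumulative_displacement(self) -> np.ndarray:
        return self.positions - self.reference.vertices

    def deformed_mesh(self) -> TriangleMesh:
        return self.reference.with_vertices(self.positions)


def solve_system(system: LinearSystem) -> tuple[np.ndarray, float]:
    """LU-solve A·x = B; return (displacements as an (N, dim) array, P)."""
    lu = _factorize(system.matrix)
    return _solve_with(lu, system, system.rhs)


def _factorize(matrix: np.ndarray):
    if not np.all(np.isfinite(matrix)):
        raise SolverError("non-finite entries in system matrix")
    try:
        lu, piv = scipy.linalg.lu_factor(matrix)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises ValueError too
        raise SolverError(f"LU factorization failed: {exc}") from exc
    diag = np.abs(np.diag(lu))
    if diag.min() <= 1e-14 * diag.max():
        raise SolverError(
            "singular system matrix; add boundary conditions to remove the "
            "rigid-translation mode"
        )
    return lu, piv

def _solve_with(lu_piv, system: LinearSystem, rhs: np.ndarray) -> tuple[np.ndarray, float]:
    x = scipy.linalg.lu_solve(lu_piv, rhs)
    residual = np.max(np.abs(system.matrix @ x - rhs))
    if not np.all(np.isfinite(x)):
        raise SolverError("non-finite solution")
    if residual > 1e-8 * (1.0 + np.max(np.abs(rhs))):
        raise SolverError(f"linear solve residual {residual:g} too large")
    n, dim = system.n_vertices, system.dim
    u = x[: dim * n].reshape(dim, n).T
    return u, float(x[-1])


def _volume_residual(s_vectors: np.ndarray, u: np.ndarray) -> float:
    """Normalized volume-conservation residual |Σ S_i·u_i| of one increment."""
    num = abs(float(np.sum(s_vectors * u)))
    den = float(np.sum(np.linalg.norm(s_vectors, axis=1)) * np.max(np.abs(u))) or 1.0
    return num / den


def _contact_fraction(step: int, n_steps: int, sign: float, mode: str) -> float:
    if mode == "ramp":
        return sign / n_steps
    # final_step: apply the whole force on the last loading increment,
    # remove it on the first unloading increment
    if sign > 0:
        return 1.0 if step == n_steps else 0.0
    return -1.0 if step == 1 else 0.0


def _run_ramp(
    reference: TriangleMesh,
    start_positions: np.ndarray,
    material: MaterialParams,
    load: LoadCase,
    options: SolverOptions,
    fibers: FiberSet,
    sign: float,
    start_pressure: float = 0.0,
) -> DeformationState:
    options.check()
    n_steps = options.n_steps
    positions = start_positions.copy()
    pressure = start_pressure
    history: list[StepRecord] = []
    lu = None
    system = None
    prev_pair_disp: np.ndarray | None = None
    if options.mode == "linear_reuse":
        fa, topo, va = surface_geometry(reference)
        system = assemble_matrix(reference, va, fibers, topo, material, load)
        lu = _factorize(system.matrix)
    for step in range(1, n_steps + 1):
        current = reference.with_vertices(positions)
        fa, topo, va = surface_geometry(current)
        if options.mode == "nonlinear_refactor":
            system = assemble_matrix(
                current, va, fibers, topo, material, load, prev_pair_disp
            )
            lu = _factorize(system.matrix)
        rhs = assemble_rhs(
            current,
            va,
            material,
            load,
            step_fraction=sign / n_steps,
            contact_fraction=_contact_fraction(step, n_steps, sign, load.contact_mode),
        )
        try:
            u, dp = _solve_with(lu, system, rhs)
        except SolverError as exc:
            raise SolverError(f"step {step}/{n_steps}: {exc}") from exc
        positions = positions + u
        pressure += dp
        vres = _volume_residual(system.vertex_area_vectors, u)
        if vres > options.volume_residual_tolerance:
            raise SolverError(
                f"step {step}/{n_steps}: volume residual {vres:g} exceeds "
                f"{options.volume_residual_tolerance:g}"
            )
        if options.mode == "nonlinear_refactor":
            du = u[:, None, :] - u[None, :, :]
            prev_pair_disp = np.linalg.norm(du, axis=2)
        history.append(
            StepRecord(step, step * sign / n_steps, dp, float(np.max(np.abs(u))), vres)
        )
    return DeformationState(reference, positions, pressure, n_steps, history)


def prepare_fibers(mesh: TriangleMesh) -> FiberSet:
    """Build the all-pairs fiber set and cull fibers leaving a concave body."""
    fa, topo, _ = surface_geometry(mesh)
    return cull_concave_fibers(build_fibers(mesh), mesh, fa, topo)


def run_quasistatic(
    mesh: TriangleMesh,
    material: MaterialParams,
    load: LoadCase,
    options: SolverOptions | None = None,
    fibers: FiberSet | None = None,
) -> DeformationState:
    """Ramp the loads from zero to full over ``options.n_steps`` increments."""
    options = options or SolverOptions()
    if fibers is None:
        fibers = prepare_fibers(mesh)
    return _run_ramp(mesh, mesh.vertices.copy(), material, load, options, fibers, +1.0)


def decompress(
    state: DeformationState,
    material: MaterialParams,
    load: LoadCase,
    options: SolverOptions | None = None,
    fibers: FiberSet | None = None,
) -> DeformationState:
    """Remove the loads again, in the same number of increments, starting from
    the deformed geometry.  In ``linear_reuse`` mode the matrix is the one
    factorized from the *reference* configuration, as during compression."""
    options = options or SolverOptions()
    if fibers is None:
        fibers = prepare_fibers(state.reference)
    result = _run_ramp(
        state.reference,
        state.positions.copy(),
        material,
        load,
        options,
        fibers,
        -1.0,
        start_pressure=state.pressure_variation,
    )
    result.history = state.history + result.history
    result.step_index = state.step_index + options.n_steps
    return result


def compress_decompress_cycle(
    mesh: TriangleMesh,
    material: MaterialParams,
    load: LoadCase,
    options: SolverOptions | None = None,
    fibers: FiberSet | None = None,
) -> tuple[DeformationState, DeformationState]:
    """Full load–unload cycle; returns (compressed, decompressed) states."""
    if fibers is None:
        fibers = prepare_fibers(mesh)
    compressed = run_quasistatic(mesh, material, load, options, fibers)
    final = decompress(compressed, material, load, options, fibers)
    return compressed, final
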