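"""Assembly of the quasi-static linear system A·x = B.

For a mesh with N vertices in d dimensions the system has dN+1 unknowns:
the displacement components (x-block, then y-block, then z-block) followed by
the internal pressure variation P.  Rows per vertex/axis express force
balance; the last row is the volume-conservation constraint Σ S_i·u_i = 0.

Fiber stiffness between vertices i and j along axis q:

    k_ij = Y_q (|S_i| + |S_j|) / (2 (N_i − 1) |s_i − s_j|)

where N_i − 1 is the effective connection count of vertex i (the factor that
keeps Y a discretization-independent material constant).  Surface-tension
fibers act between edge-adjacent vertices with

    t_ik = γ (|S_i| + |S_k|) / (2 |s_i − s_k|²).

The off-diagonal entry for the pair is −k (resp. −t); the diagonal is the
positive row sum, giving the restoring form k (u_i − u_j).  The pressure
column and the volume row both carry +S_i per component, a symmetric
convention; with it the sign of the solved P is opposite to a pressure that
pushes outward along S_i.  Boundary conditions are imposed by overwriting
the diagonal of each constrained degree of freedom with a large penalty
(default 1e9), which forces its solved displacement toward zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .fibers import FiberSet
from .geometry import VertexAreas, VertexTopology
from .mesh import TriangleMesh

__all__ = [
    "MaterialParams",
    "LoadCase",
    "LinearSystem",
    "assemble_matrix",
    "assemble_rhs",
    "apply_boundary_conditions",
    "fixed_cap_constraints",
]

AXES = {"x": 0, "y": 1, "z": 2}

#: type of a nonlinear stiffness rule: maps the (N, N) matrix of previous-step
#: pair displacement magnitudes |Δu_ij| to an (N, N) matrix of Y_ij values
StiffnessRule = Callable[[np.ndarray], np.ndarray]


@dataclass
class MaterialParams:
    """Material constants: per-axis Young's moduli (force/area), surface
    tension γ (force/length) and fluid density ρ (mass/volume).

    ``young_modulus`` may be a scalar (isotropic) or one value per axis.
    ``stiffness_rule``, if given, replaces the constant Y with Y_ij computed
    from the previous step's pair displacements (nonlinear stress–strain);
    it applies to all axes.
    """

    young_modulus: float | Sequence[float] = 0.0
    surface_tension: float = 0.0
    fluid_density: float = 0.0
    stiffness_rule: StiffnessRule | None = None

    def moduli(self, dim: int) -> np.ndarray:
        y = np.atleast_1d(np.asarray(self.young_modulus, dtype=float))
        if y.size == 1:
            y = np.full(dim, y[0])
        if y.size != dim:
            raise ValueError(f"need 1 or {dim} Young's moduli, got {y.size}")
        if np.any(y < 0) or self.surface_tension < 0 or self.fluid_density < 0:
            raise ValueError("moduli, surface tension and density must be >= 0")
        return y


@dataclass
class LoadCase:
    """External loads and boundary conditions.

    ``contact_forces`` is an (N, dim) array (or None); ``gravity`` is the
    downward acceleration magnitude along the vertical (last) axis;
    ``constraints`` lists (vertex, axis) index pairs fixed to the support;
    ``penalty`` is the diagonal value imposing them.  ``contact_mode`` is
    "ramp" (forces ramped with the load) or "final_step" (full force applied
    only on the last increment, removed on the first decompression increment).
    """

    contact_forces: np.ndarray | None = None
    gravity: float = 0.0
    constraints: Sequence[tuple[int, int]] = field(default_factory=list)
    penalty: float = 1e9
    contact_mode: str = "ramp"

    def forces(self, n: int, dim: int) -> np.ndarray:
        if self.contact_forces is None:
            return np.zeros((n, dim))
        f = np.asarray(self.contact_forces, dtype=float)
        if f.shape != (n, dim):
            raise ValueError(f"contact_forces must have shape {(n, dim)}")
        return f

    def check(self, n: int, dim: int) -> None:
        self.forces(n, dim)
        for vi, ax in self.constraints:
            if not (0 <= vi < n) or not (0 <= ax < dim):
                raise ValueError(f"constraint ({vi}, {ax}) out of range")
        if self.contact_mode not in ("ramp", "final_step"):
            raise ValueError(f"unknown contact_mode {self.contact_mode!r}")


@dataclass
class LinearSystem:
    """Dense (dN+1)-square system with the block ordering
    [u_x(1..N), u_y(1..N), (u_z(1..N)), P]."""

    matrix: np.ndarray
    rhs: np.ndarray
    n_vertices: int
    dim: int
    vertex_area_vectors: np.ndarray  # S_i used in the volume row, (N, dim)

    @property
    def size(self) -> int:
        return self.dim * self.n_vertices + 1

    def dof(self, vertex: int, axis: int) -> int:
        return axis * self.n_vertices + vertex


def _pair_stiffness(
    mesh: TriangleMesh,
    vareas: VertexAreas,
    fibers: FiberSet,
    topology: VertexTopology,
    material: MaterialParams,
    previous_pair_disp: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (fiber coupling matrix per unit Y, surface coupling matrix).

    The fiber matrix F[i, j] = (|S_i|+|S_j|) / (2 (N_i−1) d_ij) on active
    pairs (row-normalized by vertex i's effective count); multiplied by the
    axis modulus, or elementwise by Y_ij from the stiffness rule.
    """
    n = mesh.n_vertices
    s = vareas.magnitudes
    diff = mesh.vertices[:, None, :] - mesh.vertices[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    eff = fibers.effective_count.astype(float)
    if np.any(eff < 2):
        raise ValueError("a vertex has fewer than 2 effective connections")
    pair_area = s[:, None] + s[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        fiber = np.where(fibers.active, pair_area / (2.0 * eff[:, None] * dist), 0.0)
    if not np.all(np.isfinite(fiber)):
        raise ValueError("zero fiber length encountered during assembly")
    if previous_pair_disp is not None and material.stiffness_rule is not None:
        yij = np.asarray(material.stiffness_rule(previous_pair_disp), dtype=float)
        fiber = fiber * yij
    surface = np.zeros((n, n))
    if material.surface_tension != 0.0:
        adj = np.zeros((n, n), dtype=bool)
        for i, nbrs in enumerate(topology.edge_neighbors):
            adj[i, nbrs] = True
        with np.errstate(divide="ignore", invalid="ignore"):
            surface = np.where(
                adj, material.surface_tension * pair_area / (2.0 * dist**2), 0.0
            )
    return fiber, surface


def assemble_matrix(
    mesh: TriangleMesh,
    vareas: VertexAreas,
    fibers: FiberSet,
    topology: VertexTopology,
    material: MaterialParams,
    load: LoadCase,
    previous_pair_disp: np.ndarray | None = None,
) -> LinearSystem:
    """Assemble the full system matrix (rhs left zero); boundary penalties are
    applied by :func:`apply_boundary_conditions`."""
    n, dim = mesh.n_vertices, mesh.dim
    load.check(n, dim)
    moduli = material.moduli(dim)
    fiber, surface = _pair_stiffness(
        mesh, vareas, fibers, topology, material, previous_pair_disp
    )
    size = dim * n + 1
    a = np.zeros((size, size))
    use_rule = previous_pair_disp is not None and material.stiffness_rule is not None
    for ax in range(dim):
        block = (fiber if use_rule else moduli[ax] * fiber) + surface
        coupling = -block
        np.fill_diagonal(coupling, 0.0)
        np.fill_diagonal(coupling, block.sum(axis=1))
        sl = slice(ax * n, (ax + 1) * n)
        a[sl, sl] = coupling
        a[sl, -1] = vareas.area_vectors[:, ax]
        a[-1, sl] = vareas.area_vectors[:, ax]
    a[-1, -1] = 0.0
    system = LinearSystem(a, np.zeros(size), n, dim, vareas.area_vectors.copy())
    return apply_boundary_conditions(system, load)


def assemble_rhs(
    mesh: TriangleMesh,
    vareas: VertexAreas,
    material: MaterialParams,
    load: LoadCase,
    step_fraction: float = 1.0,
    contact_fraction: float | None = None,
) -> np.ndarray:
    """Right-hand side for one load increment, on the *current* geometry.

    Per vertex/axis: F_contact · f_c + ρ h_i (a · f) S_i,  where f is the
    increment fraction, f_c the contact-force fraction (defaults to f), and
    h_i the vertical drop from the topmost vertex.  The last entry is 0
    (volume conservation).
    """
    n, dim = mesh.n_vertices, mesh.dim
    if contact_fraction is None:
        contact_fraction = step_fraction
    forces = load.forces(n, dim) * contact_fraction
    b = np.zeros(dim * n + 1)
    vertical = mesh.vertices[:, -1]
    h = vertical.max() - vertical
    hydro = material.fluid_density * h * (load.gravity * step_fraction)
    for ax in range(dim):
        b[ax * n : (ax + 1) * n] = forces[:, ax] + hydro * vareas.area_vectors[:, ax]
    return b


def apply_boundary_conditions(system: LinearSystem, load: LoadCase) -> LinearSystem:
    """Overwrite the diagonal of each constrained degree of freedom with the
    penalty value.  Off-diagonal entries are left untouched."""
    n, dim = system.n_vertices, system.dim
    if len(set(load.constraints)) >= n * dim and n > 0:
        import warnings

        warnings.warn("all degrees of freedom constrained; body is rigid")
    max_coupling = float(np.max(np.abs(system.matrix[:-1, :-1]))) if n else 0.0
    if max_coupling > 0 and load.penalty / max_coupling < 1e3:
        import warnings

        warnings.warn(
            f"penalty {load.penalty:g} is < 1e3 × the largest coupling "
            f"{max_coupling:g}; constraints may leak"
        )
    for vi, ax in load.constraints:
        k = system.dof(vi, ax)
        system.matrix[k, k] = load.penalty
    return system


def fixed_cap_constraints(mesh: TriangleMesh, cap_height: float) -> list[tuple[int, int]]:
    """Fully fix every vertex within ``cap_height`` of the topmost vertex
    (the paper-style spherical-cap support)."""
    vertical = mesh.vertices[:, -1]
    cap = np.nonzero(vertical >= vertical.max() - cap_height)[0]
    return [(int(i), ax) for i in cap for ax in range(mesh.dim)]
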