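"""Shared fixtures and independent geometric oracles."""

from __future__ import annotations

import numpy as np
import pytest

import fiberfluid as ff


@pytest.fixture(scope="session")
def rectangle():
    """The worked 2D rectangle with corners (±15, ±20)."""
    return ff.make_rectangle(15.0, 20.0)


@pytest.fixture(scope="session")
def octahedron():
    return ff.make_platonic("octahedron", 1.0)


@pytest.fixture(scope="session")
def icosahedron():
    return ff.make_platonic("icosahedron", 1.0)


@pytest.fixture(scope="session")
def icosphere1():
    return ff.make_icosphere(1, 1.0)


@pytest.fixture(scope="session")
def icosphere2():
    return ff.make_icosphere(2, 1.0)


@pytest.fixture(scope="session")
def lprism():
    return ff.make_lprism()


@pytest.fixture(scope="session")
def icosphere2_fibers(icosphere2):
    """Culled fiber set for the 162-vertex sphere (expensive; share it)."""
    return ff.prepare_fibers(icosphere2)


def rectangle_load(penalty: float = 1e9) -> ff.LoadCase:
    """Worked-example loads: 1680 upward at both upper corners; lower-left
    fixed, lower-right vertically constrained."""
    forces = np.zeros((4, 2))
    forces[0, 1] = 1680.0  # upper-right
    forces[3, 1] = 1680.0  # upper-left
    return ff.LoadCase(
        contact_forces=forces,
        constraints=[(2, 0), (2, 1), (1, 1)],
        penalty=penalty,
    )


def rectangle_system(mesh: ff.TriangleMesh) -> ff.LinearSystem:
    fa, topo, va = ff.surface_geometry(mesh)
    fibers = ff.build_fibers(mesh)
    mat = ff.MaterialParams(young_modulus=360.0)
    load = rectangle_load()
    system = ff.assemble_matrix(mesh, va, fibers, topo, mat, load)
    system.rhs = ff.assemble_rhs(mesh, va, mat, load, 1.0)
    return system


def solid_angle(mesh: ff.TriangleMesh, point: np.ndarray) -> float:
    """Total solid angle of the closed surface seen from ``point``
    (Van Oosterom–Strackee); ≈4π inside, ≈0 outside, ≈2π on a face."""
    v = mesh.vertices - point
    total = 0.0
    for a, b, c in mesh.faces:
        va, vb, vc = v[a], v[b], v[c]
        num = np.dot(va, np.cross(vb, vc))
        la, lb, lc = np.linalg.norm(va), np.linalg.norm(vb), np.linalg.norm(vc)
        den = la * lb * lc + np.dot(va, vb) * lc + np.dot(va, vc) * lb + np.dot(vb, vc) * la
        total += 2.0 * np.arctan2(num, den)
    return abs(total)


def classify_point(mesh: ff.TriangleMesh, point: np.ndarray) -> str:
    """'in', 'out' or 'boundary' by winding number with a wide safety band."""
    w = solid_angle(mesh, point)
    if w < np.pi:
        return "out"
    if w > 3.0 * np.pi:
        return "in"
    return "boundary"


def oracle_fiber_classification(mesh: ff.TriangleMesh, i: int, j: int) -> str:
    """Classify fiber (i, j) by sampling interior points at the quartiles:
    'cull' if any sample is outside, 'keep' if all are inside, 'ambiguous'
    if any sample lies on the surface (boundary chords are undecidable)."""
    p, q = mesh.vertices[i], mesh.vertices[j]
    classes = [classify_point(mesh, p + t * (q - p)) for t in (0.25, 0.5, 0.75)]
    if "boundary" in classes:
        return "ambiguous"
    return "cull" if "out" in classes else "keep"
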