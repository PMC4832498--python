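"""Quantitative evaluation: cycle reversibility and surface-area validation.

The reversibility metric measures the discretization error of the
incremental scheme: after a full load–unload cycle the mean residual vertex
displacement, normalized by the bounding-box diagonal of the initial mesh,

    r = Σ_i |u_i| / (N · sqrt(Δx² + Δy² + Δz²)),

is zero for the continuous problem and shrinks like 1/n with the number of
load increments n.

The area report reproduces the analytic cross-check: for solids inscribed in
a unit sphere the computed face-area and vertex-area totals are compared with
the closed-form surface areas (octahedron 4√3 R², icosahedron
40√3/(5+√5) R², sphere 4πR²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import surface_geometry
from .mesh import TriangleMesh, make_icosphere, make_platonic

__all__ = [
    "ReversibilityResult",
    "reversibility_error",
    "area_validation_report",
    "standard_area_fixtures",
]

OCTAHEDRON_AREA = 4.0 * math.sqrt(3.0)
ICOSAHEDRON_AREA = 40.0 * math.sqrt(3.0) / (5.0 + math.sqrt(5.0))
SPHERE_AREA = 4.0 * math.pi


@dataclass
class ReversibilityResult:
    mean_normalized_residual: float
    bounding_box_diagonal: float
    per_vertex_residuals: np.ndarray

    @property
    def percent(self) -> float:
        return 100.0 * self.mean_normalized_residual


def reversibility_error(initial: TriangleMesh, final: TriangleMesh) -> ReversibilityResult:
    """Mean residual displacement between corresponding vertices, normalized
    by the initial mesh's bounding-box diagonal."""
    if initial.n_vertices != final.n_vertices or initial.dim != final.dim:
        raise ValueError("meshes must have the same vertex count and dimension")
    u = final.vertices - initial.vertices
    residuals = np.linalg.norm(u, axis=1)
    extents = initial.vertices.max(axis=0) - initial.vertices.min(axis=0)
    diagonal = float(np.linalg.norm(extents))
    if diagonal == 0.0:
        raise ValueError("initial mesh has zero extent")
    metric = float(residuals.sum() / (initial.n_vertices * diagonal))
    return ReversibilityResult(metric, diagonal, residuals)


def standard_area_fixtures(radius: float = 1.0) -> list[tuple[str, TriangleMesh, float]]:
    """(name, mesh, analytic area) for the unit-circumradius validation set."""
    r2 = radius * radius
    return [
        ("octahedron", make_platonic("octahedron", radius), OCTAHEDRON_AREA * r2),
        ("icosahedron", make_platonic("icosahedron", radius), ICOSAHEDRON_AREA * r2),
        ("icosphere3", make_icosphere(3, radius), SPHERE_AREA * r2),
    ]


def area_validation_report(
    fixtures: list[tuple[str, TriangleMesh, float]] | None = None,
) -> pd.DataFrame:
    """One row per fixture: vertex/face counts, analytic area, Σ|A_i|, Σ|S_i|
    and the number of agreeing significant figures with the analytic value."""
    if fixtures is None:
        fixtures = standard_area_fixtures()
    rows = []
    for name, mesh, analytic in fixtures:
        fa, topo, va = surface_geometry(mesh)
        rel = abs(fa.total_face_area - analytic) / abs(analytic)
        sig_figs = math.inf if rel == 0 else math.floor(-math.log10(rel))
        rows.append(
            {
                "object": name,
                "n_vertices": mesh.n_vertices,
                "n_faces": mesh.n_faces,
                "analytic_area": analytic,
                "sum_face_areas": fa.total_face_area,
                "sum_vertex_areas": va.total_vertex_area,
                "sig_figs_vs_analytic": sig_figs,
            }
        )
    return pd.DataFrame(rows)
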