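"""Face and vertex area vectors of a surface mesh.

Each triangular face i carries an outward area vector A_i (half the cross
product of two edge vectors).  Each vertex i carries an area vector

    S_i = C * sum_k A_k   over the faces k incident to i,

with a single global normalization constant

    C = (sum_i |A_i|) / (sum_i |sum_k A_k|)

chosen so that the vertex areas add up to the true surface area,
sum_i |S_i| = sum_i |A_i|.  The vertex area determines the surface force a
pressure exerts at that vertex.

In 2D the "faces" are boundary edges and A_i is the outward edge normal
scaled by the edge length; the same vertex-area formula applies over the two
incident edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TriangleMesh

__all__ = [
    "FaceAreas",
    "VertexTopology",
    "VertexAreas",
    "face_area_vectors",
    "vertex_face_adjacency",
    "vertex_area_vectors",
    "surface_geometry",
]


@dataclass
class FaceAreas:
    """Per-face outward area vectors A_i and their magnitudes."""

    area_vectors: np.ndarray  # (N', dim)
    magnitudes: np.ndarray  # (N',)
    total_face_area: float
    degenerate_faces: list[int]


@dataclass
class VertexTopology:
    """Vertex→face incidence and edge-neighbor lists."""

    shared_faces: list[np.ndarray]
    n_faces_sharing: np.ndarray
    edge_neighbors: list[np.ndarray]


@dataclass
class VertexAreas:
    """Per-vertex area vectors S_i, normalized so Σ|S_i| = Σ|A_i|."""

    area_vectors: np.ndarray  # (N, dim)
    magnitudes: np.ndarray  # (N,)
    total_vertex_area: float
    normalization_constant: float


def face_area_vectors(mesh: TriangleMesh) -> FaceAreas:
    """Outward area vector of every face (3D) or boundary edge (2D).

    Degenerate faces contribute a zero vector and are flagged rather than
    aborting (scanned meshes contain slivers).
    """
    v = mesh.vertices
    if mesh.dim == 3:
        a, b, c = mesh.faces.T
        vectors = 0.5 * np.cross(v[b] - v[a], v[c] - v[a])
    else:
        a, b = mesh.faces.T
        edge = v[b] - v[a]
        # orientation from the polygon's signed area: CCW -> rotate edge -90°,
        # CW -> rotate +90°; either way the normal points outward
        signed_area = 0.5 * float(np.sum(v[a, 0] * v[b, 1] - v[a, 1] * v[b, 0]))
        if signed_area >= 0:
            vectors = np.column_stack([edge[:, 1], -edge[:, 0]])
        else:
            vectors = np.column_stack([-edge[:, 1], edge[:, 0]])
    magnitudes = np.linalg.norm(vectors, axis=1)
    scale = float(np.max(magnitudes)) if len(magnitudes) else 1.0
    degenerate = [int(i) for i in np.nonzero(magnitudes <= 1e-12 * max(scale, 1.0))[0]]
    return FaceAreas(vectors, magnitudes, float(magnitudes.sum()), degenerate)


def vertex_face_adjacency(mesh: TriangleMesh) -> VertexTopology:
    """For each vertex: the incident faces and the vertices joined to it by a
    mesh edge.  Raises on isolated vertices (they carry no area)."""
    shared: list[list[int]] = [[] for _ in range(mesh.n_vertices)]
    neighbors: list[set[int]] = [set() for _ in range(mesh.n_vertices)]
    for fi, face in enumerate(mesh.faces):
        for k, vi in enumerate(face):
            shared[vi].append(fi)
            for other in face:
                if other != vi:
                    neighbors[vi].add(int(other))
    counts = np.array([len(s) for s in shared])
    if np.any(counts == 0):
        lonely = int(np.nonzero(counts == 0)[0][0])
        raise ValueError(f"vertex {lonely} belongs to no face")
    return VertexTopology(
        [np.array(s, dtype=int) for s in shared],
        counts,
        [np.array(sorted(n), dtype=int) for n in neighbors],
    )


def vertex_area_vectors(face_areas: FaceAreas, topology: VertexTopology) -> VertexAreas:
    """Vertex area vectors S_i = C·Σ_k A_k with the global normalization C."""
    n = len(topology.shared_faces)
    dim = face_areas.area_vectors.shape[1]
    raw = np.zeros((n, dim))
    for i, faces in enumerate(topology.shared_faces):
        raw[i] = face_areas.area_vectors[faces].sum(axis=0)
    raw_norms = np.linalg.norm(raw, axis=1)
    denom = float(raw_norms.sum())
    if denom == 0.0:
        raise ValueError("all vertex area sums vanish; mesh is degenerate")
    c = face_areas.total_face_area / denom
    vectors = c * raw
    magnitudes = c * raw_norms
    return VertexAreas(vectors, magnitudes, float(magnitudes.sum()), c)


def surface_geometry(mesh: TriangleMesh) -> tuple[FaceAreas, VertexTopology, VertexAreas]:
    """Convenience: compute all three geometry products for a mesh."""
    fa = face_area_vectors(mesh)
    topo = vertex_face_adjacency(mesh)
    return fa, topo, vertex_area_vectors(fa, topo)
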