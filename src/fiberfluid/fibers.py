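"""All-pairs elastic fiber network and concave-fiber culling.

Every pair of surface vertices is joined by an elastic fiber; the set of all
fibers fills the body with long-range connections, replacing a volumetric
mesh.  On a convex body every fiber lies inside the solid.  On a concave body
some straight chords exit the surface and must be removed; two geometric
tests detect them:

1. a *local outward test* at each endpoint — if the fiber direction has a
   positive component along the outward normal of any face incident to the
   endpoint, the fiber leaves the body there;
2. a *segment–triangle intersection test* against every face not incident to
   either endpoint.

After culling, the per-vertex number of surviving connections (the effective
connection count) replaces N−1 in the stiffness normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import FaceAreas, VertexTopology
from .mesh import TriangleMesh

__all__ = [
    "FiberSet",
    "build_fibers",
    "local_outward_test",
    "segment_triangle_intersect",
    "reflex_vertices",
    "cull_concave_fibers",
]

# tolerances: _OUTWARD_TOL keeps surface chords whose outward dot is only
# rounding noise; _GRAZE_TOL absorbs floating-point noise in the plane and
# barycentric classifications of the intersection test
_OUTWARD_TOL = 1e-9
_GRAZE_TOL = 1e-12


@dataclass
class FiberSet:
    """Symmetric active-pair relation with rest lengths.

    ``active`` and ``rest_length`` are (N, N); the diagonal is inactive.
    ``effective_count[i]`` is the number of active connections at vertex i —
    N−1 on a convex body, fewer after concave culling.
    """

    active: np.ndarray  # (N, N) bool
    rest_length: np.ndarray  # (N, N) float

    @property
    def n_vertices(self) -> int:
        return self.active.shape[0]

    @property
    def effective_count(self) -> np.ndarray:
        return self.active.sum(axis=1)

    @property
    def n_fibers(self) -> int:
        return int(self.active.sum()) // 2

    def pairs(self) -> np.ndarray:
        """Active pairs (i, j) with i < j, shape (n_fibers, 2)."""
        i, j = np.nonzero(np.triu(self.active, k=1))
        return np.column_stack([i, j])


def build_fibers(mesh: TriangleMesh) -> FiberSet:
    """Connect every vertex pair; rest lengths from current positions."""
    n = mesh.n_vertices
    if n < 2:
        raise ValueError("need at least 2 vertices to build fibers")
    diff = mesh.vertices[:, None, :] - mesh.vertices[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    off = ~np.eye(n, dtype=bool)
    if np.any(dist[off] == 0.0):
        i, j = np.argwhere((dist == 0.0) & off)[0]
        raise ValueError(f"vertices {i} and {j} coincide; zero-length fiber")
    return FiberSet(active=off, rest_length=dist)


def local_outward_test(
    i: int,
    j: int,
    face_areas: FaceAreas,
    topology: VertexTopology,
    mesh: TriangleMesh,
) -> bool:
    """True if the fiber (i, j) stays inside the body near vertex i.

    Checks A_k·(s_i − s_j) for every face k incident to i; a (significantly)
    negative value means the fiber direction points outward through face k.
    """
    d = mesh.vertices[i] - mesh.vertices[j]
    areas = face_areas.area_vectors[topology.shared_faces[i]]
    dots = areas @ d
    thresh = -_OUTWARD_TOL * np.linalg.norm(d) * face_areas.magnitudes[topology.shared_faces[i]]
    return bool(np.all(dots >= thresh))


def segment_triangle_intersect(p: np.ndarray, q: np.ndarray, tri: np.ndarray) -> bool:
    """True iff the open segment (p, q) crosses the interior of triangle ``tri``.

    Segments lying on the triangle's plane or touching it only at an endpoint
    do not count as crossing; a transversal crossing through the triangle's
    boundary does.  Degenerate triangles return False.
    """
    hits = _segment_hits_triangles(
        np.asarray(p, float), np.asarray(q, float), np.asarray(tri, float)[None, :, :]
    )
    return bool(hits[0])


def _segment_hits_triangles(p: np.ndarray, q: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Vectorized strict-interior segment/triangle crossing test.

    ``tris`` is (M, 3, dim3).  Signed-distance check against each triangle's
    plane, then a barycentric containment test at the crossing point with a
    strict interior margin.
    """
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    n = np.cross(b - a, c - a)
    n_norm = np.linalg.norm(n, axis=1)
    valid = n_norm > 0.0
    seg_len = np.linalg.norm(q - p)
    eps = _GRAZE_TOL
    dp = np.einsum("ij,ij->i", n, p - a)
    dq = np.einsum("ij,ij->i", n, q - a)
    scale = n_norm * max(seg_len, 1e-300)
    # strict plane crossing: endpoints on opposite sides, neither on the plane
    crosses = valid & (dp * dq < 0) & (np.abs(dp) > eps * scale) & (np.abs(dq) > eps * scale)
    if not crosses.any():
        return crosses
    idx = np.nonzero(crosses)[0]
    t = dp[idx] / (dp[idx] - dq[idx])
    x = p + t[:, None] * (q - p)
    # barycentric coordinates w.r.t. triangle (a, b, c)
    v0 = b[idx] - a[idx]
    v1 = c[idx] - a[idx]
    v2 = x - a[idx]
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    denom = d00 * d11 - d01 * d01
    ok = denom > 0.0
    v = np.where(ok, (d11 * d20 - d01 * d21) / np.where(ok, denom, 1.0), -1.0)
    w = np.where(ok, (d00 * d21 - d01 * d20) / np.where(ok, denom, 1.0), -1.0)
    u = 1.0 - v - w
    # inclusive containment: a transversal crossing through a triangle's
    # boundary edge still means the segment touches the surface there.  A
    # strictly interior chord can never do this, and chords along mesh edges
    # are protected upstream by the incident-face exclusion and by the strict
    # plane-crossing requirement (coplanar and endpoint-on-plane cases pass).
    margin = -_GRAZE_TOL
    inside = (u > margin) & (v > margin) & (w > margin)
    out = np.zeros_like(crosses)
    out[idx] = inside
    return out


def reflex_vertices(mesh: TriangleMesh, face_areas: FaceAreas) -> np.ndarray:
    """Boolean mask of vertices touching a reflex edge (interior dihedral
    angle > π).  At such vertices the solid is locally non-convex and the
    outward-normal dot-product test is not decisive: the inward directions
    form a union, not an intersection, of face half-spaces."""
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, (a, b, c) in enumerate(mesh.faces):
        for e in ((a, b), (b, c), (c, a)):
            key = (e[0], e[1]) if e[0] < e[1] else (e[1], e[0])
            edge_faces.setdefault(key, []).append(fi)
    reflex = np.zeros(mesh.n_vertices, dtype=bool)
    v = mesh.vertices
    for (a, b), faces in edge_faces.items():
        if len(faces) != 2:
            continue
        n1 = face_areas.area_vectors[faces[0]]
        other = [p for p in mesh.faces[faces[1]] if p != a and p != b][0]
        d = v[other] - v[a]
        if np.dot(n1, d) > _OUTWARD_TOL * np.linalg.norm(n1) * np.linalg.norm(d):
            reflex[a] = reflex[b] = True
    return reflex


def cull_concave_fibers(
    fibers: FiberSet,
    mesh: TriangleMesh,
    face_areas: FaceAreas,
    topology: VertexTopology,
) -> FiberSet:
    """Deactivate fibers that leave the solid; recompute effective counts.

    A fiber is removed if the local outward test fails at either endpoint or
    if it crosses any triangle not incident to an endpoint.  The local test
    is applied only at locally convex endpoints: at a vertex on a reflex edge
    the inward cone is a union of half-spaces and the any-negative rule would
    cull strictly interior fibers, so such endpoints rely on the intersection
    test alone.  Runs once on the undeformed geometry; connectivity is frozen
    across load steps.
    """
    if mesh.dim == 2:
        # the only 2D fixture is a convex polygon; chords of a convex polygon
        # never exit, so culling is the identity
        return FiberSet(fibers.active.copy(), fibers.rest_length.copy())
    active = fibers.active.copy()
    v = mesh.vertices
    tris = v[mesh.faces]  # (M, 3, 3)
    tri_lo = tris.min(axis=1)
    tri_hi = tris.max(axis=1)
    n_faces = mesh.n_faces
    incident = [set(topology.shared_faces[i].tolist()) for i in range(mesh.n_vertices)]
    reflex = reflex_vertices(mesh, face_areas)
    for i, j in fibers.pairs():
        keep = (reflex[i] or local_outward_test(i, j, face_areas, topology, mesh)) and (
            reflex[j] or local_outward_test(j, i, face_areas, topology, mesh)
        )
        if keep:
            excluded = incident[i] | incident[j]
            cand = np.ones(n_faces, dtype=bool)
            cand[list(excluded)] = False
            p, q = v[i], v[j]
            lo, hi = np.minimum(p, q), np.maximum(p, q)
            cand &= np.all(tri_hi >= lo, axis=1) & np.all(tri_lo <= hi, axis=1)
            if cand.any():
                if _segment_hits_triangles(p, q, tris[cand]).any():
                    keep = False
        if not keep:
            active[i, j] = active[j, i] = False
    counts = active.sum(axis=1)
    if np.any(counts == 0):
        lonely = int(np.nonzero(counts == 0)[0][0])
        raise ValueError(f"vertex {lonely} lost all fiber connections")
    return FiberSet(active=active, rest_length=fibers.rest_length.copy())
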