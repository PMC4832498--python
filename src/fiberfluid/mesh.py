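"""Triangle-mesh data model, Wavefront OBJ I/O and deterministic fixture generators.

The solver operates on closed, consistently oriented triangular surface meshes
(3D) or closed boundary polygons (2D).  Vertices and faces are stored 0-based
internally; OBJ files use the format's 1-based convention and are converted on
read/write.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TriangleMesh",
    "MeshValidationReport",
    "MeshFormatError",
    "read_obj",
    "write_obj",
    "make_rectangle",
    "make_platonic",
    "make_icosphere",
    "make_lprism",
    "validate_mesh",
]

_GOLDEN = (1.0 + math.sqrt(5.0)) / 2.0

#: decimal places used for vertex coordinates in written OBJ files
OBJ_PRECISION = 10


class MeshFormatError(ValueError):
    """Raised for malformed OBJ input or unsupported mesh output."""


@dataclass
class TriangleMesh:
    """A surface mesh: ``vertices`` is (N, dim); ``faces`` is (N', 3) triangles
    in 3D or (N', 2) boundary edges in 2D, 0-based.

    In 3D the face winding encodes outward orientation (counter-clockwise seen
    from outside); in 2D the edge traversal direction plays the same role.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] not in (2, 3):
            raise ValueError("vertices must be (N, 2) or (N, 3)")
        per_face = 3 if self.dim == 3 else 2
        if self.faces.size == 0:
            self.faces = self.faces.reshape(0, per_face)
        if self.faces.ndim != 2 or self.faces.shape[1] != per_face:
            raise ValueError(f"faces must be (M, {per_face}) for dim={self.dim}")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
                raise ValueError("face index out of range")
            for row in self.faces:
                if len(set(row.tolist())) != per_face:
                    raise ValueError(f"face {row.tolist()} repeats a vertex")

    @property
    def dim(self) -> int:
        return self.vertices.shape[1]

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        """Same connectivity, new vertex positions."""
        return TriangleMesh(np.asarray(vertices, dtype=float), self.faces.copy())


@dataclass
class MeshValidationReport:
    is_closed: bool
    is_consistently_oriented: bool
    signed_volume: float
    degenerate_faces: list[int] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return (
            self.is_closed
            and self.is_consistently_oriented
            and self.signed_volume > 0
            and not self.degenerate_faces
        )


# ---------------------------------------------------------------------------
# OBJ I/O (minimal dialect: v and f records; vt/vn indices stripped)
# ---------------------------------------------------------------------------

def read_obj(path: str | Path) -> TriangleMesh:
    """Read a triangulated Wavefront OBJ file.

    Only ``v`` and ``f`` records are consumed; ``f`` entries may carry
    ``/vt/vn`` suffixes, which are dropped.  Faces must be triangles and
    indices must be positive and in range.
    """
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            tag = parts[0]
            if tag == "v":
                if len(parts) < 4:
                    raise MeshFormatError(f"line {lineno}: vertex needs 3 coordinates")
                vertices.append([float(p) for p in parts[1:4]])
            elif tag == "f":
                idx = parts[1:]
                if len(idx) != 3:
                    raise MeshFormatError(
                        f"line {lineno}: face has {len(idx)} vertices, only triangles supported"
                    )
                face = []
                for token in idx:
                    i = int(token.split("/")[0])
                    if i < 1 or i > len(vertices):
                        raise MeshFormatError(f"line {lineno}: vertex index {i} out of range")
                    face.append(i - 1)
                faces.append(face)
            # vn/vt/other records are ignored
    if not vertices:
        raise MeshFormatError(f"{path}: no vertices found")
    return TriangleMesh(np.array(vertices), np.array(faces, dtype=int).reshape(-1, 3))


def write_obj(mesh: TriangleMesh, path: str | Path) -> None:
    """Write a 3D mesh as OBJ (``v`` records then ``f`` records, 1-based).

    Coordinates are printed with :data:`OBJ_PRECISION` decimal places.
    """
    if mesh.dim != 3:
        raise MeshFormatError("OBJ output supports 3D triangle meshes only")
    if mesh.n_vertices == 0:
        raise MeshFormatError("refusing to write an empty mesh")
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.{OBJ_PRECISION}f} {v[1]:.{OBJ_PRECISION}f} {v[2]:.{OBJ_PRECISION}f}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


# ---------------------------------------------------------------------------
# Fixture generators
# ---------------------------------------------------------------------------

def make_rectangle(half_width: float, half_height: float) -> TriangleMesh:
    """2D rectangle with corners (±half_width, ±half_height).

    Vertex order is fixed: 0 = upper-right, 1 = lower-right, 2 = lower-left,
    3 = upper-left, with the four boundary edges traversed in that order.
    The edge "area vectors" are the outward edge normals scaled by the edge
    lengths (2·half_width horizontally, 2·half_height vertically).
    """
    if half_width <= 0 or half_height <= 0:
        raise ValueError("rectangle half-dimensions must be positive")
    w, h = float(half_width), float(half_height)
    vertices = np.array([[w, h], [w, -h], [-w, -h], [-w, h]])
    edges = np.array([[0, 1], [1, 2], [2, 3], [3, 0]])
    return TriangleMesh(vertices, edges)


def _fix_convex_outward(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Flip faces of a convex solid so every normal points away from the centroid."""
    centroid = vertices.mean(axis=0)
    fixed = faces.copy()
    for i, (a, b, c) in enumerate(faces):
        n = np.cross(vertices[b] - vertices[a], vertices[c] - vertices[a])
        if np.dot(n, vertices[[a, b, c]].mean(axis=0) - centroid) < 0:
            fixed[i] = [a, c, b]
    return fixed


def make_platonic(name: str, circumradius: float = 1.0) -> TriangleMesh:
    """Triangulated Platonic solid with all vertices on a sphere of the given radius."""
    if circumradius <= 0:
        raise ValueError("circumradius must be positive")
    name = name.lower()
    if name == "tetrahedron":
        verts = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        ) / math.sqrt(3.0)
        faces = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    elif name == "octahedron":
        verts = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=float,
        )
        faces = np.array(
            [[0, 2, 4], [2, 1, 4], [1, 3, 4], [3, 0, 4],
             [2, 0, 5], [1, 2, 5], [3, 1, 5], [0, 3, 5]]
        )
    elif name == "icosahedron":
        p = _GOLDEN
        verts = np.array(
            [[-1, p, 0], [1, p, 0], [-1, -p, 0], [1, -p, 0],
             [0, -1, p], [0, 1, p], [0, -1, -p], [0, 1, -p],
             [p, 0, -1], [p, 0, 1], [-p, 0, -1], [-p, 0, 1]],
            dtype=float,
        ) / math.sqrt(1.0 + p * p)
        faces = np.array(
            [[0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
             [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
             [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
             [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1]]
        )
    else:
        raise ValueError(f"unknown Platonic solid {name!r}")
    verts = verts * float(circumradius)
    return TriangleMesh(verts, _fix_convex_outward(verts, faces))


def make_icosphere(subdivisions: int, radius: float = 1.0) -> TriangleMesh:
    """Icosphere: recursive midpoint subdivision of an icosahedron with radial
    projection onto the sphere of the given radius.

    Counts follow N' = 20·4^k, N = 2 + N'/2: 12/20 → 42/80 → 162/320 → 642/1280.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be non-negative")
    base = make_platonic("icosahedron", radius)
    verts = [v for v in base.vertices]
    faces = base.faces.tolist()
    for _ in range(subdivisions):
        midpoint_cache: dict[tuple[int, int], int] = {}

        def midpoint(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            if key not in midpoint_cache:
                m = 0.5 * (verts[a] + verts[b])
                m *= radius / np.linalg.norm(m)
                midpoint_cache[key] = len(verts)
                verts.append(m)
            return midpoint_cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
        faces = new_faces
    return TriangleMesh(np.array(verts), np.array(faces, dtype=int))


def make_lprism(leg: float = 2.0, thickness: float = 1.0, depth: float = 1.0) -> TriangleMesh:
    """Closed concave fixture: an L-shaped cross-section extruded along z.

    The L occupies [0, leg]×[0, thickness] ∪ [0, thickness]×[0, leg] in the
    xy-plane; 12 vertices, 20 faces.  Used to exercise concave fiber culling.
    """
    if not (0 < thickness < leg) or depth <= 0:
        raise ValueError("require 0 < thickness < leg and depth > 0")
    L, t, d = float(leg), float(thickness), float(depth)
    poly = np.array([[0, 0], [L, 0], [L, t], [t, t], [t, L], [0, L]])
    bottom = np.column_stack([poly, np.zeros(6)])
    top = np.column_stack([poly, np.full(6, d)])
    vertices = np.vstack([bottom, top])
    faces = []
    # caps: fan from corner 0 (valid for this L); bottom wound downward, top upward
    for i in range(1, 5):
        faces.append([0, i + 1, i])
        faces.append([6, 6 + i, 6 + i + 1])
    # side walls, outward for the CCW cross-section
    for i in range(6):
        j = (i + 1) % 6
        faces.append([i, j, 6 + j])
        faces.append([i, 6 + j, 6 + i])
    return TriangleMesh(vertices, np.array(faces, dtype=int))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_mesh(mesh: TriangleMesh) -> MeshValidationReport:
    """Report closedness, orientation consistency, signed volume and degenerate
    faces.  Never raises on a bad mesh — it only reports."""
    if mesh.dim == 2:
        return _validate_2d(mesh)
    directed: dict[tuple[int, int], int] = {}
    for a, b, c in mesh.faces:
        for e in ((a, b), (b, c), (c, a)):
            directed[e] = directed.get(e, 0) + 1
    undirected: dict[tuple[int, int], int] = {}
    for (a, b), cnt in directed.items():
        key = (a, b) if a < b else (b, a)
        undirected[key] = undirected.get(key, 0) + cnt
    is_closed = all(cnt == 2 for cnt in undirected.values()) and bool(undirected)
    is_oriented = is_closed and all(
        directed.get((a, b), 0) == 1 and directed.get((b, a), 0) == 1
        for (a, b) in undirected
    )
    v = mesh.vertices
    signed_volume = float(
        sum(
            np.dot(v[a], np.cross(v[b], v[c])) for a, b, c in mesh.faces
        ) / 6.0
    )
    scale = float(np.max(np.abs(v))) or 1.0
    degenerate = [
        int(i)
        for i, (a, b, c) in enumerate(mesh.faces)
        if np.linalg.norm(np.cross(v[b] - v[a], v[c] - v[a])) <= 1e-12 * scale**2
    ]
    return MeshValidationReport(is_closed, is_oriented, signed_volume, degenerate)


def _validate_2d(mesh: TriangleMesh) -> MeshValidationReport:
    heads = np.bincount(mesh.faces[:, 0], minlength=mesh.n_vertices)
    tails = np.bincount(mesh.faces[:, 1], minlength=mesh.n_vertices)
    is_closed = bool(mesh.n_faces) and bool(np.all(heads + tails == 2))
    is_oriented = is_closed and bool(np.all(heads == 1) and np.all(tails == 1))
    v = mesh.vertices
    signed_area = float(
        0.5 * sum(v[a, 0] * v[b, 1] - v[a, 1] * v[b, 0] for a, b in mesh.faces)
    )
    scale = float(np.max(np.abs(v))) or 1.0
    degenerate = [
        int(i)
        for i, (a, b) in enumerate(mesh.faces)
        if np.linalg.norm(v[b] - v[a]) <= 1e-12 * scale
    ]
    # the rectangle fixture winds clockwise (y-up); |area| is what matters
    return MeshValidationReport(is_closed, is_oriented, abs(signed_area), degenerate)
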