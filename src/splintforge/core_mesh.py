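"""Triangle-mesh data model, STL I/O, signed distance fields and surface metrics.

Everything downstream (splint-base construction, the signed-distance-field
Boolean, the swept-silhouette undercut removal) moves through the
:class:`TriangleMesh` container defined here.  All coordinates are millimetres;
STL files are read and written as millimetres, matching the clinical CAD
convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels

__all__ = [
    "TriangleMesh",
    "DistanceField",
    "STLParseError",
    "read_stl",
    "write_stl",
    "signed_distance",
    "unsigned_distance",
    "mesh_volume",
    "is_watertight",
    "mean_surface_distance",
    "sample_surface",
    "merge_duplicate_vertices",
    "weld_vertices",
]

STL_HEADER = b"splintforge"
#: vertex-merge tolerance applied on STL read (mm); STL duplicates vertices
#: per facet, and edge-manifold checks need them merged back
STL_MERGE_TOL = 1e-8

_BINARY_RECORD = np.dtype(
    [("normal", "<f4", (3,)), ("vertices", "<f4", (3, 3)), ("attr", "<u2")]
)


class STLParseError(ValueError):
    """Raised when an STL file is malformed; message names the byte offset."""


@dataclass
class TriangleMesh:
    """Indexed triangle surface in mm.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array
        Vertex-index triples; consistent counter-clockwise winding viewed
        from outside for a watertight outward-oriented solid.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face index out of range")
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise ValueError("face repeats a vertex")

    # -- derived quantities -------------------------------------------------

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) coordinates of each face."""
        return self.vertices[self.faces]

    @property
    def face_normals(self) -> np.ndarray:
        t = self.triangles
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        norm = np.linalg.norm(n, axis=1)
        norm[norm == 0] = 1.0
        return n / norm[:, None]

    @property
    def face_areas(self) -> np.ndarray:
        t = self.triangles
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )

    @property
    def face_centroids(self) -> np.ndarray:
        return self.triangles.mean(axis=1)

    @property
    def area(self) -> float:
        return float(self.face_areas.sum())

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) min/max corner of the axis-aligned bounding box."""
        if not len(self.vertices):
            return np.zeros((2, 3))
        return np.array([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    @property
    def bbox_diagonal(self) -> float:
        b = self.bounds
        return float(np.linalg.norm(b[1] - b[0]))

    @property
    def is_empty(self) -> bool:
        return len(self.faces) == 0

    def euler_characteristic(self) -> int:
        """V - E + F with E counted over unique undirected edges."""
        e = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        n_edges = len(np.unique(e, axis=0))
        return len(self.vertices) - n_edges + len(self.faces)

    # -- constructive helpers ----------------------------------------------

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    def flipped(self) -> "TriangleMesh":
        """Same surface with all face windings (and hence normals) reversed."""
        return TriangleMesh(self.vertices.copy(), self.faces[:, ::-1].copy())

    def translated(self, offset) -> "TriangleMesh":
        return TriangleMesh(self.vertices + np.asarray(offset, float), self.faces.copy())

    def transformed(self, rotation, translation=(0.0, 0.0, 0.0)) -> "TriangleMesh":
        r = np.asarray(rotation, float)
        return TriangleMesh(
            self.vertices @ r.T + np.asarray(translation, float), self.faces.copy()
        )

    @staticmethod
    def concatenate(meshes) -> "TriangleMesh":
        meshes = [m for m in meshes if len(m.faces)]
        if not meshes:
            return TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))
        verts = []
        faces = []
        offset = 0
        for m in meshes:
            verts.append(m.vertices)
            faces.append(m.faces + offset)
            offset += len(m.vertices)
        return TriangleMesh(np.vstack(verts), np.vstack(faces))

    @staticmethod
    def empty() -> "TriangleMesh":
        return TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


@dataclass
class DistanceField:
    """Signed distances (mm) of query points to a closed surface.

    Negative inside, positive outside; magnitude is the Euclidean distance to
    the nearest surface point.
    """

    points: np.ndarray
    values: np.ndarray


# ---------------------------------------------------------------------------
# topology / measure
# ---------------------------------------------------------------------------


def is_watertight(mesh: TriangleMesh) -> bool:
    """True iff every edge is shared by exactly two consistently wound faces."""
    if mesh.is_empty:
        return False
    directed = mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    # duplicated directed edge => inconsistent winding or non-manifold
    uniq_dir = np.unique(directed, axis=0)
    if len(uniq_dir) != len(directed):
        return False
    undirected = np.sort(directed, axis=1)
    _, counts = np.unique(undirected, axis=0, return_counts=True)
    return bool(np.all(counts == 2))


def mesh_volume(mesh: TriangleMesh) -> float:
    """Signed enclosed volume (mm^3) by the divergence theorem.

    Positive for a watertight outward-oriented surface; the sign flips when
    all faces are reversed.
    """
    if mesh.is_empty:
        return 0.0
    t = mesh.triangles
    return float(np.einsum("ij,ij->", t[:, 0], np.cross(t[:, 1], t[:, 2])) / 6.0)


# ---------------------------------------------------------------------------
# distance queries
# ---------------------------------------------------------------------------


class _SurfaceQuery:
    """Exact nearest-surface distance with KD-tree candidate pruning.

    The nearest face centroid gives an upper bound on the true distance;
    every face whose centroid lies within (bound + max face circumradius)
    is then tested exactly.
    """

    def __init__(self, mesh: TriangleMesh):
        if mesh.is_empty:
            raise ValueError("cannot build distance query for an empty mesh")
        self.tri = np.ascontiguousarray(mesh.triangles)
        centroids = self.tri.mean(axis=1)
        self.radii = np.linalg.norm(
            self.tri - centroids[:, None, :], axis=2
        ).max(axis=1)
        self.r_max = float(self.radii.max())
        self.tree = cKDTree(centroids)

    def distances(self, points: np.ndarray, chunk: int = 16384) -> np.ndarray:
        points = np.ascontiguousarray(points, dtype=np.float64).reshape(-1, 3)
        if not len(points):
            return np.zeros(0)
        out = np.empty(len(points))
        # chunked: the ball-query candidate lists dominate memory
        for lo in range(0, len(points), chunk):
            pts = points[lo : lo + chunk]
            _, idx = self.tree.query(pts)
            upper = _kernels.point_face_distances(pts, self.tri, idx.astype(np.int64))
            radius = upper + self.r_max + 1e-12
            lists = self.tree.query_ball_point(pts, radius)
            counts = np.fromiter((len(l) for l in lists), dtype=np.int64, count=len(pts))
            indptr = np.zeros(len(pts) + 1, dtype=np.int64)
            np.cumsum(counts, out=indptr[1:])
            indices = (
                np.concatenate([np.asarray(l, dtype=np.int64) for l in lists])
                if indptr[-1]
                else np.zeros(0, dtype=np.int64)
            )
            out[lo : lo + chunk] = _kernels.min_distance_csr(
                pts, self.tri, indptr, indices, upper
            )
        return out


def unsigned_distance(mesh: TriangleMesh, points) -> np.ndarray:
    """Unsigned distance (mm) from each query point to the mesh surface."""
    return _SurfaceQuery(mesh).distances(np.asarray(points, float))


def winding_number(mesh: TriangleMesh, points) -> np.ndarray:
    """Generalized winding number of each point (~1 inside, ~0 outside)."""
    points = np.ascontiguousarray(points, dtype=np.float64).reshape(-1, 3)
    tri = np.ascontiguousarray(mesh.triangles)
    return _kernels.winding_numbers(points, tri)


def signed_distance(mesh: TriangleMesh, points, check: bool = True) -> DistanceField:
    """Signed distance field: negative inside the closed surface.

    Raises ``ValueError`` for a non-watertight mesh (the sign would be
    undefined).  The inside test uses the generalized winding number with a
    0.5 threshold.
    """
    if check and not is_watertight(mesh):
        raise ValueError("signed_distance requires a watertight mesh")
    points = np.ascontiguousarray(points, dtype=np.float64).reshape(-1, 3)
    d = unsigned_distance(mesh, points)
    inside = winding_number(mesh, points) > 0.5
    values = np.where(inside, -d, d)
    return DistanceField(points=points, values=values)


# ---------------------------------------------------------------------------
# surface sampling and distance metrics
# ---------------------------------------------------------------------------


def sample_surface(mesh: TriangleMesh, n_samples: int, rng) -> np.ndarray:
    """Area-uniform random points on the surface (face choice by area,
    position by the square-root barycentric trick)."""
    areas = mesh.face_areas
    total = areas.sum()
    if total <= 0:
        raise ValueError("mesh has zero surface area")
    fi = rng.choice(len(areas), size=n_samples, p=areas / total)
    r1 = np.sqrt(rng.random(n_samples))
    r2 = rng.random(n_samples)
    t = mesh.triangles[fi]
    return (
        (1.0 - r1)[:, None] * t[:, 0]
        + (r1 * (1.0 - r2))[:, None] * t[:, 1]
        + (r1 * r2)[:, None] * t[:, 2]
    )


def mean_surface_distance(
    a: TriangleMesh,
    b: TriangleMesh,
    n_samples: int = 20_000,
    seed: int = 0,
) -> float:
    """Symmetric mean surface distance (mm) between two surfaces.

    Averages the unsigned distance of ``n_samples`` area-uniform samples on
    A to surface B, and the same from B to A, then averages both directions.
    Deterministic for a fixed seed.
    """
    if a.is_empty or b.is_empty:
        raise ValueError("mean_surface_distance requires non-empty meshes")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    samples_a = sample_surface(a, n_samples, rng)
    samples_b = sample_surface(b, n_samples, rng)
    d_ab = _SurfaceQuery(b).distances(samples_a).mean()
    d_ba = _SurfaceQuery(a).distances(samples_b).mean()
    return float(0.5 * (d_ab + d_ba))


# ---------------------------------------------------------------------------
# vertex merging
# ---------------------------------------------------------------------------


def merge_duplicate_vertices(
    vertices: np.ndarray, faces: np.ndarray, tol: float = STL_MERGE_TOL
) -> TriangleMesh:
    """Merge exactly-coincident vertices by grid quantization at ``tol``.

    Keeps the first-occurrence coordinates unchanged; drops faces that
    degenerate to fewer than three distinct vertices.
    """
    vertices = np.asarray(vertices, float).reshape(-1, 3)
    faces = np.asarray(faces, np.int64).reshape(-1, 3)
    if not len(vertices):
        return TriangleMesh.empty()
    keys = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(
        keys, axis=0, return_index=True, return_inverse=True
    )
    # preserve first-occurrence ordering so output is deterministic
    order = np.argsort(first, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_faces = rank[inverse][faces]
    keep = ~(
        (new_faces[:, 0] == new_faces[:, 1])
        | (new_faces[:, 1] == new_faces[:, 2])
        | (new_faces[:, 0] == new_faces[:, 2])
    )
    return TriangleMesh(vertices[first[order]], new_faces[keep])


def weld_vertices(mesh: TriangleMesh, tol: float, face_data: np.ndarray | None = None):
    """Cluster vertices closer than ``tol`` (union-find over KD-tree pairs).

    Unlike quantization this merges across grid boundaries; used to fuse
    Boolean seams.  Degenerate and cancelling duplicate faces are dropped.
    When ``face_data`` (one row per face) is given, the matching rows of the
    surviving faces are returned alongside the mesh.
    """
    if mesh.is_empty:
        if face_data is not None:
            return mesh.copy(), face_data.copy()
        return mesh.copy()
    pairs = cKDTree(mesh.vertices).query_pairs(tol, output_type="ndarray")
    parent = np.arange(len(mesh.vertices))

    def find(i):
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    roots = np.array([find(i) for i in range(len(parent))])
    uniq, inverse = np.unique(roots, return_inverse=True)
    new_faces = inverse[mesh.faces]
    data = face_data if face_data is not None else np.zeros((len(new_faces), 0))
    keep = ~(
        (new_faces[:, 0] == new_faces[:, 1])
        | (new_faces[:, 1] == new_faces[:, 2])
        | (new_faces[:, 0] == new_faces[:, 2])
    )
    new_faces = new_faces[keep]
    data = data[keep]
    # cancel exact duplicate faces: opposite-winding duplicates annihilate,
    # same-winding duplicates collapse to one
    key = np.sort(new_faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    keep2 = np.ones(len(new_faces), dtype=bool)
    for group in np.flatnonzero(counts > 1):
        members = np.flatnonzero(inv == group)
        # pair up opposite orientations; an odd leftover survives
        survivors = []
        for m in members:
            cancelled = False
            for k, s in enumerate(survivors):
                if set(new_faces[m]) == set(new_faces[s]) and not np.array_equal(
                    _canonical(new_faces[m]), _canonical(new_faces[s])
                ):
                    survivors.pop(k)
                    keep2[s] = False
                    keep2[m] = False
                    cancelled = True
                    break
            if not cancelled:
                survivors.append(m)
        # collapse same-orientation duplicates among survivors
        seen = {}
        for m in survivors:
            c = tuple(_canonical(new_faces[m]))
            if c in seen:
                keep2[m] = False
            else:
                seen[c] = m
    out = TriangleMesh(mesh.vertices[uniq], new_faces[keep2])
    if face_data is not None:
        return out, data[keep2]
    return out


def _canonical(face) -> np.ndarray:
    """Rotate a face so its smallest index comes first (winding preserved)."""
    i = int(np.argmin(face))
    return np.roll(face, -i)


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------


def read_stl(path) -> TriangleMesh:
    """Read a binary or ASCII STL file (auto-detected), merging duplicated
    per-facet vertices at :data:`STL_MERGE_TOL`."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if _looks_ascii(raw):
        tris = _parse_ascii(raw, path)
    else:
        tris = _parse_binary(raw, path)
    n = len(tris)
    verts = tris.reshape(-1, 3).astype(np.float64)
    faces = np.arange(3 * n, dtype=np.int64).reshape(-1, 3)
    return merge_duplicate_vertices(verts, faces, STL_MERGE_TOL)


def _looks_ascii(raw: bytes) -> bool:
    head = raw[:512].lstrip()
    if not head.startswith(b"solid"):
        return False
    # binary files sometimes start with "solid" too; require ascii keywords
    return b"facet" in raw[:1024] or b"endsolid" in raw[:1024]


def _parse_binary(raw: bytes, path) -> np.ndarray:
    if len(raw) < 84:
        raise STLParseError(
            f"{path}: binary STL truncated at byte {len(raw)} (need 84-byte header)"
        )
    count = int(np.frombuffer(raw[80:84], dtype="<u4")[0])
    expected = 84 + 50 * count
    if len(raw) != expected:
        raise STLParseError(
            f"{path}: record count {count} at byte offset 80 implies "
            f"{expected} bytes, file has {len(raw)}"
        )
    records = np.frombuffer(raw[84:], dtype=_BINARY_RECORD)
    return records["vertices"].astype(np.float64)


_FLOAT_RE = re.compile(
    rb"vertex\s+([-+0-9.eE]+)\s+([-+0-9.eE]+)\s+([-+0-9.eE]+)"
)


def _parse_ascii(raw: bytes, path) -> np.ndarray:
    matches = _FLOAT_RE.findall(raw)
    if not matches:
        raise STLParseError(f"{path}: ASCII STL contains no vertex records")
    try:
        verts = np.array([[float(x) for x in m] for m in matches])
    except ValueError as exc:
        raise STLParseError(f"{path}: unparsable vertex value: {exc}") from exc
    if len(verts) % 3:
        raise STLParseError(
            f"{path}: vertex count {len(verts)} is not a multiple of 3"
        )
    return verts.reshape(-1, 3, 3)


def write_stl(mesh: TriangleMesh, path, dialect: str = "binary") -> None:
    """Write the mesh as STL.  ``dialect`` is ``binary`` (default) or
    ``ascii``; coordinates are stored at 32-bit float precision either way."""
    if mesh.is_empty:
        raise ValueError("refusing to write an empty mesh")
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"unknown STL dialect {dialect!r}")
    tris = mesh.triangles.astype(np.float32)
    # normals derived from the 32-bit coordinates actually stored, so that
    # write -> read -> write is byte-identical
    t64 = tris.astype(np.float64)
    n = np.cross(t64[:, 1] - t64[:, 0], t64[:, 2] - t64[:, 0])
    norm = np.linalg.norm(n, axis=1)
    norm[norm == 0] = 1.0
    normals = (n / norm[:, None]).astype(np.float32)
    if dialect == "binary":
        records = np.zeros(len(tris), dtype=_BINARY_RECORD)
        records["normal"] = normals
        records["vertices"] = tris
        header = STL_HEADER.ljust(80, b"\0")
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(np.uint32(len(tris)).tobytes())
            fh.write(records.tobytes())
    else:
        lines = ["solid splintforge"]
        for n, t in zip(normals, tris):
            lines.append(f" facet normal {n[0]:.8e} {n[1]:.8e} {n[2]:.8e}")
            lines.append("  outer loop")
            for v in t:
                lines.append(f"   vertex {v[0]:.8e} {v[1]:.8e} {v[2]:.8e}")
            lines.append("  endloop")
            lines.append(" endfacet")
        lines.append("endsolid splintforge\n")
        with open(path, "w") as fh:
            fh.write("\n".join(lines))
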