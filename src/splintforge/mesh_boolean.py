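"""Boolean operations on watertight triangle meshes via signed distance fields.

Three stages, mirroring classic surface-Boolean practice:

1. *Split*: compute all pairwise triangle-triangle intersection segments,
   chain them into seam polylines, and constrained-retriangulate every
   intersected face so the seam is embedded as mesh edges.
2. *Classify*: evaluate the signed distance of each split cell's centroid
   against the other solid.  Centroids are strictly off-seam, so the sign is
   well defined even for seam-adjacent cells.
3. *Extract*: difference keeps A-cells at non-negative distance from B plus
   B-cells at non-positive distance from A (the B patch flipped so the
   result stays outward-oriented); union keeps non-negative/non-negative;
   intersection non-positive/non-positive.  Seam vertices are welded so the
   result is watertight.

Exactly coplanar face-face contact (common in CAD fixtures, rare in
clinical meshes) is resolved by a deterministic symbolic perturbation of B
and one retry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import polygonize, unary_union

from . import _triangulate
from .core_mesh import (
    TriangleMesh,
    is_watertight,
    mesh_volume,
    signed_distance,
    weld_vertices,
)

__all__ = [
    "SplitPair",
    "CoplanarContactError",
    "split_at_intersection",
    "classify_cells",
    "boolean",
]

#: seam snap tolerance, as a fraction of the joint bounding-box diagonal;
#: must sit far below JITTER_REL or welding would crush the thin features
#: that symbolic perturbation legitimately creates
SEAM_TOL_REL = 1e-12
#: symbolic-perturbation scale for coplanar contact, same normalization
JITTER_REL = 1e-9
#: centroid classification tolerance; must sit far below JITTER_REL, or the
#: coincident patches that symbolic perturbation separates would be kept on
#: both sides again
CLS_TOL_REL = 1e-12


class CoplanarContactError(RuntimeError):
    """Two faces overlap in a common plane; the intersection curve is not a
    segment and the split is ill-defined without perturbation."""


@dataclass
class SplitPair:
    """Both meshes refined so their intersection curve is embedded as edges.

    ``A_probes``/``B_probes`` hold one off-seam classification probe point
    per face: the centroid for ordinary faces, the source arrangement
    polygon's representative point for zero-area pieces (whose centroid
    would sit exactly on the seam).
    """

    A_split: TriangleMesh
    B_split: TriangleMesh
    seam: list  # list of (k, 3) polyline arrays, closed where the curve closes
    A_probes: np.ndarray | None = None
    B_probes: np.ndarray | None = None


# ---------------------------------------------------------------------------
# triangle-triangle intersection
# ---------------------------------------------------------------------------


def _tri_tri_segment(t1: np.ndarray, t2: np.ndarray, eps_plane: float):
    """Intersection segment of two triangles (Moller interval method).

    Returns a (2, 3) array, ``None`` for no/point contact, or raises
    :class:`CoplanarContactError` for overlapping coplanar faces.
    """
    n1 = np.cross(t1[1] - t1[0], t1[2] - t1[0])
    n2 = np.cross(t2[1] - t2[0], t2[2] - t2[0])
    d2 = (t2 - t1[0]) @ n1 / (np.linalg.norm(n1) + 1e-300)
    d1 = (t1 - t2[0]) @ n2 / (np.linalg.norm(n2) + 1e-300)
    if np.all(np.abs(d2) < eps_plane) or np.all(np.abs(d1) < eps_plane):
        # coplanar candidate; overlap iff 2D projections intersect with area
        if Polygon(t1[:, _drop_axis(n1)]).intersection(
            Polygon(t2[:, _drop_axis(n1)])
        ).area > 0:
            raise CoplanarContactError("coplanar overlapping faces")
        return None
    if not (np.any(d2 > eps_plane) and np.any(d2 < -eps_plane)):
        return None
    if not (np.any(d1 > eps_plane) and np.any(d1 < -eps_plane)):
        return None
    axis = np.cross(n1, n2)
    s1 = _plane_crossing(t1, d1, eps_plane)
    s2 = _plane_crossing(t2, d2, eps_plane)
    if s1 is None or s2 is None:
        return None
    p1 = s1 @ axis
    p2 = s2 @ axis
    if p1[0] > p1[1]:
        p1 = p1[::-1]
        s1 = s1[::-1]
    if p2[0] > p2[1]:
        p2 = p2[::-1]
        s2 = s2[::-1]
    lo = max(p1[0], p2[0])
    hi = min(p1[1], p2[1])
    if hi - lo <= 0:
        return None
    start = s1[0] if p1[0] >= p2[0] else s2[0]
    end = s1[1] if p1[1] <= p2[1] else s2[1]
    if np.array_equal(start, end):
        return None
    return np.array([start, end])


def _drop_axis(normal: np.ndarray):
    keep = [0, 1, 2]
    keep.pop(int(np.argmax(np.abs(normal))))
    return keep


def _plane_crossing(tri: np.ndarray, dist: np.ndarray, eps: float):
    """The two points where a triangle's edges cross the other plane.

    Vertices within ``eps`` of the plane count as on-plane crossing points.
    """
    sides = np.where(dist > eps, 1, np.where(dist < -eps, -1, 0))
    pts = []
    for i in range(3):
        if sides[i] == 0:
            pts.append(tri[i])
    for i in range(3):
        j = (i + 1) % 3
        if sides[i] * sides[j] == -1:
            t = dist[i] / (dist[i] - dist[j])
            pts.append(tri[i] + t * (tri[j] - tri[i]))
    if len(pts) != 2:
        return None
    return np.array(pts)


# ---------------------------------------------------------------------------
# broad phase
# ---------------------------------------------------------------------------


def _candidate_pairs(a: TriangleMesh, b: TriangleMesh, margin: float, chunk: int = 16384):
    """Face index pairs whose AABBs overlap (KD-tree centroid prefilter,
    chunked over B to bound the candidate-list memory)."""
    ta, tb = a.triangles, b.triangles
    ca, cb = ta.mean(axis=1), tb.mean(axis=1)
    ra = np.linalg.norm(ta - ca[:, None], axis=2).max(axis=1)
    rb = np.linalg.norm(tb - cb[:, None], axis=2).max(axis=1)
    tree = cKDTree(ca)
    lo_a, hi_a = ta.min(axis=1), ta.max(axis=1)
    lo_b, hi_b = tb.min(axis=1), tb.max(axis=1)
    pairs = []
    for lo in range(0, len(tb), chunk):
        lists = tree.query_ball_point(
            cb[lo : lo + chunk], rb[lo : lo + chunk] + ra.max() + margin
        )
        for off, cand in enumerate(lists):
            if not cand:
                continue
            jb = lo + off
            cand = np.asarray(cand)
            ok = np.all(
                (lo_a[cand] <= hi_b[jb] + margin) & (hi_a[cand] >= lo_b[jb] - margin),
                axis=1,
            )
            for ja in cand[ok]:
                pairs.append((int(ja), jb))
    return pairs


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------


def split_at_intersection(a: TriangleMesh, b: TriangleMesh) -> SplitPair:
    """Embed the A/B intersection curve as shared edges in both meshes.

    Raises :class:`CoplanarContactError` on coplanar face overlap and
    ``ValueError`` for open meshes.
    """
    for name, m in (("A", a), ("B", b)):
        if not is_watertight(m):
            raise ValueError(f"mesh {name} is not watertight")
    scale = float(
        np.linalg.norm(
            np.maximum(a.bounds[1], b.bounds[1]) - np.minimum(a.bounds[0], b.bounds[0])
        )
    )
    eps_plane = 1e-12 * max(scale, 1.0)
    eps_seam = SEAM_TOL_REL * max(scale, 1.0)

    pairs = _candidate_pairs(a, b, eps_seam)
    ta, tb = a.triangles, b.triangles
    segs = []  # (2,3) arrays
    seg_faces_a: dict[int, list[int]] = {}
    seg_faces_b: dict[int, list[int]] = {}
    for fa, fb in pairs:
        seg = _tri_tri_segment(ta[fa], tb[fb], eps_plane)
        if seg is None:
            continue
        k = len(segs)
        segs.append(seg)
        seg_faces_a.setdefault(fa, []).append(k)
        seg_faces_b.setdefault(fb, []).append(k)

    if not segs:
        return SplitPair(
            a.copy(), b.copy(), [], a.face_centroids, b.face_centroids
        )

    # snap segment endpoints: to nearby original vertices first, then to
    # each other, so both retriangulations see identical seam coordinates
    endpoints = np.array(segs).reshape(-1, 3)
    all_verts = np.vstack([a.vertices, b.vertices])
    vtree = cKDTree(all_verts)
    d, idx = vtree.query(endpoints)
    snap = d < eps_seam
    endpoints[snap] = all_verts[idx[snap]]
    endpoints = _cluster_points(endpoints, eps_seam)
    segs = endpoints.reshape(-1, 2, 3)
    live = ~np.all(segs[:, 0] == segs[:, 1], axis=1)

    a_split, a_probes = _split_mesh(a, seg_faces_a, segs, live, eps_seam)
    b_split, b_probes = _split_mesh(b, seg_faces_b, segs, live, eps_seam)
    seam = _chain_segments(segs[live])
    return SplitPair(a_split, b_split, seam, a_probes, b_probes)


def _cluster_points(points: np.ndarray, tol: float) -> np.ndarray:
    """Snap points within ``tol`` of each other to a shared representative."""
    tree = cKDTree(points)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    parent = np.arange(len(points))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    out = points.copy()
    for i in range(len(points)):
        out[i] = points[find(i)]
    return out


def _split_mesh(mesh, seg_map, segs, live, eps_seam):
    tri = mesh.triangles
    keep_faces = np.ones(len(mesh.faces), dtype=bool)
    new_tris = []
    new_probes = []
    for f, seg_ids in seg_map.items():
        f_segs = [segs[k] for k in seg_ids if live[k]]
        if not f_segs:
            continue
        pieces = _retriangulate_face(tri[f], f_segs, eps_seam)
        if pieces is None:
            continue  # degenerate arrangement; leave the face untouched
        keep_faces[f] = False
        for t, probe in pieces:
            new_tris.append(t)
            new_probes.append(probe)
    verts = [mesh.vertices]
    faces = [mesh.faces[keep_faces]]
    probes = [mesh.face_centroids[keep_faces]]
    offset = len(mesh.vertices)
    for t in new_tris:
        verts.append(t)
        faces.append(np.arange(offset, offset + 3, dtype=np.int64)[None, :])
        offset += 3
    if new_probes:
        probes.append(np.array(new_probes))
    out = TriangleMesh(np.vstack(verts), np.vstack(faces))
    # fuse the duplicated per-piece vertices back into a connected mesh
    return weld_vertices(out, eps_seam * 0.5, face_data=np.vstack(probes))


def _retriangulate_face(tri3d: np.ndarray, segments, eps_seam):
    """Split one triangle by its seam segments; returns (3, 3) arrays or
    ``None`` when the arrangement degenerates to the original face."""
    origin = tri3d[0]
    u = tri3d[1] - tri3d[0]
    u = u / np.linalg.norm(u)
    w = np.cross(tri3d[1] - tri3d[0], tri3d[2] - tri3d[0])
    w = w / np.linalg.norm(w)
    v = np.cross(w, u)

    # project every distinct 3D point exactly once (elementwise arithmetic):
    # GEOS nodes lines by *exact* coordinate equality, and the same 3D point
    # pushed through separate matmul calls can differ in the last ulp, which
    # would leave seam polylines dangling instead of splitting the face
    index: dict[bytes, int] = {}
    pts3d: list[np.ndarray] = []

    def pid(p: np.ndarray) -> int:
        key = p.tobytes()
        if key not in index:
            index[key] = len(pts3d)
            pts3d.append(p)
        return index[key]

    corner_ids = [pid(c) for c in tri3d]
    seg_ids = [
        (pid(seg[0]), pid(seg[1]))
        for seg in segments
        if np.linalg.norm(seg[1] - seg[0]) >= eps_seam * 1e-3
    ]
    if not seg_ids:
        return None
    known3d = np.array(pts3d)
    q = known3d - origin
    known2d = np.column_stack(
        [
            q[:, 0] * u[0] + q[:, 1] * u[1] + q[:, 2] * u[2],
            q[:, 0] * v[0] + q[:, 1] * v[1] + q[:, 2] * v[2],
        ]
    )
    tri2d = known2d[corner_ids]
    tri_poly = Polygon(tri2d)
    ring = LineString(np.vstack([tri2d, tri2d[:1]]))
    lines = [ring]
    for i0, i1 in seg_ids:
        s2 = known2d[[i0, i1]].copy()
        # an endpoint that lands (within float) on the triangle boundary can
        # "dangle" in the exact-predicate arrangement and fail to split the
        # face; extend such endpoints past the ring so the crossing is real,
        # and discard the outside slivers afterwards
        for k in (0, 1):
            d = ring.distance(Point(s2[k]))
            if d < eps_seam:
                axis = s2[k] - s2[1 - k]
                norm = np.linalg.norm(axis)
                if norm > 0:
                    s2[k] = s2[k] + axis / norm * (10 * eps_seam + 2 * d)
        lines.append(LineString(s2))
    faces = [
        poly
        for poly in polygonize(unary_union(lines))
        if poly.area > 0 and tri_poly.contains(poly.representative_point())
    ]
    if len(faces) <= 1:
        return None
    ktree = cKDTree(known2d)
    eps_area = 100.0 * eps_seam * eps_seam
    out = []
    for poly in faces:
        rep = poly.representative_point()
        rep3 = origin + rep.x * u + rep.y * v
        for t2 in _triangulate.triangulate_polygon(poly):
            d, idx = ktree.query(t2)
            t3 = np.empty((3, 3))
            for i in range(3):
                if d[i] < eps_seam:
                    t3[i] = known3d[idx[i]]
                else:
                    t3[i] = origin + t2[i, 0] * u + t2[i, 1] * v
            # zero-area pieces with distinct corners are kept: they carry
            # collinear seam vertices and keep edges matched across faces;
            # they are probed at their host polygon's interior point since
            # their own centroid sits exactly on the seam
            if (
                np.array_equal(t3[0], t3[1])
                or np.array_equal(t3[1], t3[2])
                or np.array_equal(t3[0], t3[2])
            ):
                continue
            probe = t3.mean(axis=0) if _area3(t3) > eps_area else rep3
            out.append((t3, probe))
    return out if out else None


def _area3(t: np.ndarray) -> float:
    return 0.5 * float(np.linalg.norm(np.cross(t[1] - t[0], t[2] - t[0])))


def _chain_segments(segs: np.ndarray) -> list:
    """Chain intersection segments into polylines via shared endpoints."""
    if not len(segs):
        return []
    pts, inverse = np.unique(
        segs.reshape(-1, 3).round(12), axis=0, return_inverse=True
    )
    edges = inverse.reshape(-1, 2)
    adj: dict[int, list[int]] = {}
    for i, (p, q) in enumerate(edges):
        adj.setdefault(int(p), []).append(i)
        adj.setdefault(int(q), []).append(i)
    used = np.zeros(len(edges), dtype=bool)
    polylines = []
    # open chains first (endpoints with odd degree), then closed loops
    starts = [p for p, es in adj.items() if len(es) % 2 == 1]
    for start_set in (starts, list(adj.keys())):
        for start in start_set:
            for e in adj[start]:
                if used[e]:
                    continue
                chain = [start]
                node, edge = start, e
                while True:
                    used[edge] = True
                    p, q = edges[edge]
                    node = int(q) if int(p) == node else int(p)
                    chain.append(node)
                    nxt = [k for k in adj[node] if not used[k]]
                    if not nxt:
                        break
                    edge = nxt[0]
                polylines.append(pts[chain])
    return polylines


# ---------------------------------------------------------------------------
# classification and the Boolean itself
# ---------------------------------------------------------------------------


def _drop_slivers(mesh: TriangleMesh, tol: float) -> TriangleMesh:
    """Remove collinear (zero-area) faces.

    Their role — carrying collinear seam vertices through the per-face
    triangulations — is over once the parts are combined: the matching
    proper faces on both sides reference the same chain vertices, and any
    imbalance left by removal is healed by the T-junction repair."""
    if mesh.is_empty:
        return mesh
    t = mesh.triangles
    areas = 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)
    edges = np.linalg.norm(t - np.roll(t, -1, axis=1), axis=2).max(axis=1)
    keep = areas > tol * edges
    if keep.all():
        return mesh
    return TriangleMesh(mesh.vertices, mesh.faces[keep])


def _fill_small_holes(mesh: TriangleMesh, max_len: int = 8) -> TriangleMesh:
    """Fan-fill boundary loops of at most ``max_len`` edges.

    Holes this small are tolerance-scale artifacts (a dropped notch
    triangle at a seam corner), not real geometry; the fan is wound
    opposite to the surviving boundary edges so orientation stays
    consistent."""
    if mesh.is_empty:
        return mesh
    directed = mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    und = np.sort(directed, axis=1)
    uniq, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    boundary = counts[inv] == 1
    if not boundary.any():
        return mesh
    # the hole must be traversed opposite to the surviving faces
    need = {(int(v), int(u)) for u, v in directed[boundary]}
    succ: dict[int, list[int]] = {}
    for u, v in need:
        succ.setdefault(u, []).append(v)
    new_faces = []
    used: set = set()
    for start in list(succ):
        for nxt in succ[start]:
            if (start, nxt) in used:
                continue
            loop = [start, nxt]
            ok = False
            while len(loop) <= max_len + 1:
                options = [
                    v for v in succ.get(loop[-1], ())
                    if (loop[-1], v) not in used and (len(loop) < 2 or v != loop[-2])
                ]
                if not options:
                    break
                loop.append(options[0])
                if loop[-1] == loop[0]:
                    ok = True
                    break
            if ok and len(loop) - 1 >= 3:
                for u, v in zip(loop[:-1], loop[1:]):
                    used.add((u, v))
                anchor = loop[0]
                for u, v in zip(loop[1:-2], loop[2:-1]):
                    if anchor not in (u, v):
                        new_faces.append([anchor, u, v])
    if not new_faces:
        return mesh
    return TriangleMesh(
        mesh.vertices, np.vstack([mesh.faces, np.array(new_faces, dtype=np.int64)])
    )


def _drop_conflict_faces(mesh: TriangleMesh) -> TriangleMesh:
    """Remove faces with two or more unbalanced (count != 2) edges.

    Grazing contact (one surface tangent to the other) can leave a
    redundant lens face whose removal restores edge balance; faces
    adjacent to an ordinary hole have only one unbalanced edge and are
    left alone."""
    if mesh.is_empty:
        return mesh
    directed = mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    und = np.sort(directed, axis=1)
    uniq, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    bad_edge = (counts[inv] != 2).reshape(-1, 3)
    keep = bad_edge.sum(axis=1) < 2
    if keep.all():
        return mesh
    return TriangleMesh(mesh.vertices, mesh.faces[keep])


def _repair_tjunctions(mesh: TriangleMesh, tol: float, max_rounds: int = 6) -> TriangleMesh:
    """Split edges that pass through a nearby existing vertex.

    Symbolic perturbation can leave T-junctions at the perturbation scale
    (a seam vertex of one operand lying on, but not part of, an edge of the
    other).  Only edges that are actually unmatched (boundary or
    non-manifold) are examined.
    """
    for _ in range(max_rounds):
        if mesh.is_empty:
            return mesh
        directed = mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
        und = np.sort(directed, axis=1)
        uniq, counts = np.unique(und, axis=0, return_counts=True)
        bad = {tuple(e) for e in uniq[counts != 2]}
        if not bad:
            return mesh
        tree = cKDTree(mesh.vertices)
        new_faces = []
        changed = False
        for face in mesh.faces:
            emitted = False
            for k in range(3):
                i, j = int(face[k]), int(face[(k + 1) % 3])
                if (min(i, j), max(i, j)) not in bad:
                    continue
                p, q = mesh.vertices[i], mesh.vertices[j]
                length = np.linalg.norm(q - p)
                if length == 0:
                    continue
                cand = tree.query_ball_point((p + q) / 2, length / 2 + tol)
                axis = (q - p) / length
                inserts = []
                for c in cand:
                    if c == i or c == j:
                        continue
                    t = (mesh.vertices[c] - p) @ axis
                    if t <= tol or t >= length - tol:
                        continue
                    if np.linalg.norm(mesh.vertices[c] - (p + t * axis)) < tol:
                        inserts.append((t, c))
                if not inserts:
                    continue
                inserts.sort()
                opposite = int(face[(k + 2) % 3])
                chain = [i] + [c for _, c in inserts] + [j]
                for a, b in zip(chain[:-1], chain[1:]):
                    if a != b and a != opposite and b != opposite:
                        new_faces.append([a, b, opposite])
                emitted = True
                break  # one edge per face per round
            if not emitted:
                new_faces.append(list(face))
            else:
                changed = True
        if not changed:
            return mesh
        mesh = TriangleMesh(mesh.vertices, np.array(new_faces, dtype=np.int64))
    return mesh


def classify_cells(
    mesh: TriangleMesh,
    reference: TriangleMesh,
    keep: str,
    tol: float | None = None,
    probes: np.ndarray | None = None,
) -> TriangleMesh:
    """Keep the cells of ``mesh`` whose centroid signed distance to
    ``reference`` is ``nonnegative`` or ``nonpositive``.

    ``mesh`` must already be split against ``reference``: centroids of split
    cells are strictly off the seam, so the centroid sign is decisive where
    a vertex-based rule (vertices sit *on* the seam at distance 0) is not.
    ``probes`` optionally overrides the per-face probe points (used for
    zero-area seam pieces, whose centroid is not off-seam).
    """
    if keep not in ("nonnegative", "nonpositive"):
        raise ValueError(f"keep must be nonnegative|nonpositive, got {keep!r}")
    if not is_watertight(reference):
        raise ValueError("reference mesh is not watertight")
    if mesh.is_empty:
        return mesh.copy()
    if tol is None:
        tol = CLS_TOL_REL * max(reference.bbox_diagonal, 1.0)
    pts = mesh.face_centroids if probes is None else probes
    d = signed_distance(reference, pts, check=False).values
    mask = d >= -tol if keep == "nonnegative" else d <= tol
    faces = mesh.faces[mask]
    used = np.unique(faces)
    remap = np.full(len(mesh.vertices), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(mesh.vertices[used], remap[faces])


def boolean(
    a: TriangleMesh,
    b: TriangleMesh,
    op: str,
    jitter: bool = True,
) -> TriangleMesh:
    """Boolean ``difference``, ``union`` or ``intersection`` of two
    watertight outward-oriented solids.

    On coplanar face contact, B is perturbed by a deterministic random
    translation of magnitude ``JITTER_REL`` x bbox diagonal (seed 0) and the
    split retried once (disable with ``jitter=False``).  An empty result is
    returned as an empty mesh, not an error.
    """
    if op not in ("difference", "union", "intersection"):
        raise ValueError(f"unknown Boolean op {op!r}")
    if a.is_empty or b.is_empty:
        if op == "intersection":
            return TriangleMesh.empty()
        if op == "union":
            return (a if b.is_empty else b).copy()
        return a.copy()  # difference
    scale = float(
        np.linalg.norm(
            np.maximum(a.bounds[1], b.bounds[1]) - np.minimum(a.bounds[0], b.bounds[0])
        )
    )
    rng = np.random.default_rng(0)
    shift = rng.uniform(-1.0, 1.0, 3)
    shift *= JITTER_REL * max(scale, 1.0) / np.linalg.norm(shift)

    def run(b_eff: TriangleMesh) -> TriangleMesh:
        pair = split_at_intersection(a, b_eff)
        keep_a = "nonpositive" if op == "intersection" else "nonnegative"
        keep_b = "nonnegative" if op == "union" else "nonpositive"
        part_a = classify_cells(pair.A_split, b_eff, keep_a, probes=pair.A_probes)
        part_b = classify_cells(pair.B_split, a, keep_b, probes=pair.B_probes)
        if op == "difference":
            part_b = part_b.flipped()
        combined = TriangleMesh.concatenate([part_a, part_b])
        if combined.is_empty:
            return combined
        tol = SEAM_TOL_REL * max(scale, 1.0)
        # zero-area faces have served their purpose (carrying collinear
        # seam vertices through the per-face triangulations); drop them
        # all, then split any long edge that runs through a chain vertex
        result = _drop_slivers(weld_vertices(combined, tol), tol)
        for attempt in range(5):
            if result.is_empty or is_watertight(result):
                return result
            if attempt >= 2:
                result = _drop_conflict_faces(result)
            result = _drop_slivers(
                weld_vertices(_repair_tjunctions(result, tol), tol), tol
            )
        if not result.is_empty and not is_watertight(result):
            # last resort for tolerance-scale notch holes
            result = weld_vertices(_fill_small_holes(result), tol)
        return result

    try:
        result = run(b)
        # tangential contact (surfaces touching along edges/vertices without
        # crossing) yields no intersection segments and an inconsistent
        # classification; like coplanar overlap, it is resolved by the
        # symbolic perturbation
        if is_watertight(result) or result.is_empty or not jitter:
            return result
    except CoplanarContactError:
        if not jitter:
            raise
    return run(b.translated(shift))  # second failure propagates
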