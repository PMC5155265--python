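"""Ear-clipping triangulation of simple 2D polygons, with hole bridging.

Used by the Boolean engine to retriangulate split faces: the faces of a
triangle's seam arrangement are simple polygons (occasionally with holes,
when a seam loop closes inside a single face).  Holes are spliced into the
outer ring by the classic max-x bridge construction, then the resulting
simple polygon is ear-clipped.  O(n^2), which is fine for the tiny polygons
this sees.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon
from shapely.geometry.polygon import orient

__all__ = ["triangulate_polygon"]


def _ring_coords(ring) -> np.ndarray:
    c = np.asarray(ring.coords, dtype=float)[:, :2]
    if np.allclose(c[0], c[-1]):
        c = c[:-1]
    return c


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def _point_in_tri(p, a, b, c, eps) -> bool:
    d1 = _cross(a, b, p)
    d2 = _cross(b, c, p)
    d3 = _cross(c, a, p)
    return d1 >= -eps and d2 >= -eps and d3 >= -eps


def _bridge_hole(outer: np.ndarray, hole: np.ndarray) -> np.ndarray:
    """Splice a (clockwise) hole ring into a (counter-clockwise) outer ring."""
    m_idx = int(np.argmax(hole[:, 0]))
    m = hole[m_idx]
    # shoot a ray +x from m; find the nearest crossing with an outer edge
    best_t = np.inf
    best_edge = -1
    best_pt = None
    n = len(outer)
    for i in range(n):
        p, q = outer[i], outer[(i + 1) % n]
        if (p[1] - m[1]) * (q[1] - m[1]) > 0:
            continue  # edge does not straddle the ray's y
        dy = q[1] - p[1]
        if dy == 0.0:
            x = max(p[0], q[0])
            if min(p[0], q[0]) <= m[0] <= max(p[0], q[0]):
                x = m[0]
        else:
            t = (m[1] - p[1]) / dy
            if t < 0.0 or t > 1.0:
                continue
            x = p[0] + t * (q[0] - p[0])
        if x >= m[0] - 1e-12 and x - m[0] < best_t:
            best_t = x - m[0]
            best_edge = i
            best_pt = np.array([x, m[1]])
    if best_edge < 0:
        # degenerate; attach to nearest outer vertex
        best_vertex = int(np.argmin(np.linalg.norm(outer - m, axis=1)))
    else:
        # candidate visible vertex: endpoint of the hit edge with larger x,
        # unless a reflex vertex lies inside triangle (m, I, candidate)
        p, q = outer[best_edge], outer[(best_edge + 1) % n]
        cand = best_edge if p[0] > q[0] else (best_edge + 1) % n
        tri = (m, best_pt, outer[cand])
        eps = 1e-12 * (1.0 + np.abs(outer).max())
        best_vertex = cand
        best_metric = np.inf
        for j in range(n):
            if j == cand:
                continue
            r = outer[j]
            if _point_in_tri(r, *tri, eps) or _point_in_tri(r, tri[0], tri[2], tri[1], eps):
                # prefer the reflex vertex closest (angle-wise) to the ray
                dist = abs(r[1] - m[1]) + abs(r[0] - m[0])
                if dist < best_metric:
                    best_metric = dist
                    best_vertex = j
    v = best_vertex
    # outer[..v], hole[m..], hole[..m], m again, back to outer[v..]
    return np.vstack(
        [
            outer[: v + 1],
            np.roll(hole, -m_idx, axis=0),
            hole[m_idx : m_idx + 1],
            outer[v : v + 1],
            outer[v + 1 :],
        ]
    )


def _ear_clip(ring: np.ndarray) -> list[np.ndarray]:
    """Triangulate a simple CCW polygon; returns a list of (3, 2) arrays.

    Zero-area ears (collinear boundary runs) are *emitted*, not skipped:
    dropping them would silently delete a boundary vertex and create
    T-junctions against neighbouring faces that still reference it.  The
    caller may discard degenerate output triangles only when their corners
    coincide exactly.
    """
    pts = list(ring)
    tris: list[np.ndarray] = []
    scale = 1.0 + max(np.abs(ring).max(), 1.0)
    eps = 1e-12 * scale * scale
    guard = 0
    while len(pts) > 3:
        n = len(pts)
        clipped = False
        degenerate_ear = None
        fallback = None
        fallback_cross = -np.inf
        for i in range(n):
            a, b, c = pts[i - 1], pts[i], pts[(i + 1) % n]
            cr = _cross(a, b, c)
            if cr < -eps:
                continue  # reflex
            contains = False
            for j in range(n):
                if j in ((i - 1) % n, i, (i + 1) % n):
                    continue
                if _point_in_tri(pts[j], a, b, c, -eps):
                    contains = True
                    break
            if contains:
                if cr > fallback_cross:
                    fallback_cross = cr
                    fallback = i
                continue
            if cr > eps:
                tris.append(np.array([a, b, c]))
                pts.pop(i)
                clipped = True
                break
            if degenerate_ear is None:
                degenerate_ear = i
        if not clipped:
            # no positive-area ear: clip a collinear one (emitting the
            # zero-area sliver keeps its boundary vertex alive), else the
            # least-reflex blocked candidate
            i = degenerate_ear if degenerate_ear is not None else (
                fallback if fallback is not None else 0
            )
            a, b, c = pts[i - 1], pts[i], pts[(i + 1) % len(pts)]
            tris.append(np.array([a, b, c]))
            pts.pop(i)
        guard += 1
        if guard > 10 * len(ring) + 100:
            raise RuntimeError("ear clipping failed to terminate")
    if len(pts) == 3:
        tris.append(np.array(pts))
    return tris


def triangulate_polygon(poly: Polygon) -> list[np.ndarray]:
    """Triangulate a shapely polygon (holes allowed) into (3, 2) coordinate
    triangles with counter-clockwise winding."""
    poly = orient(poly, sign=1.0)  # CCW exterior, CW holes
    outer = _ring_coords(poly.exterior)
    holes = [_ring_coords(r) for r in poly.interiors]
    holes = [h for h in holes if len(h) >= 3]
    # splice holes farthest-right first
    holes.sort(key=lambda h: -h[:, 0].max())
    for h in holes:
        outer = _bridge_hole(outer, h)
    return _ear_clip(outer)
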