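"""Initial splint construction from landmark lines via ruled surfaces.

A surgeon-style landmark plan consists of two ordered lists of lines — one
following the maxillary arch, one the mandibular — where each line has an
anchor point, a lateral (bucco-lingual) direction, and an inner/outer extent.
The inner endpoints and outer endpoints of each list are interpolated with
chord-length Catmull-Rom splines, the splines are densely resampled, and
four ruled sheets (occlusal top/bottom, lingual/buccal walls) plus two end
caps close the horseshoe-shaped splint blank into a watertight solid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .core_mesh import TriangleMesh, is_watertight, mesh_volume

__all__ = [
    "LandmarkLine",
    "SplintPlan",
    "adjust_line",
    "resample_line_series",
    "ruled_strip",
    "build_initial_splint",
    "load_plan",
    "save_plan",
]

PLAN_SCHEMA = "splintplan/1"


@dataclass(frozen=True)
class LandmarkLine:
    """One picked landmark: a point on the dental model plus the lateral
    axis and extents of the splint cross-section there.

    ``inner_point = anchor - inner_length * direction`` (toward the tongue),
    ``outside_point = anchor + outside_length * direction`` (toward the
    cheek).  ``direction`` is stored unit-normalized.
    """

    anchor: np.ndarray
    direction: np.ndarray
    inner_length: float
    outside_length: float

    def __post_init__(self):
        anchor = np.asarray(self.anchor, dtype=float).reshape(3)
        direction = np.asarray(self.direction, dtype=float).reshape(3)
        norm = np.linalg.norm(direction)
        if norm == 0:
            raise ValueError("line direction must be non-zero")
        if self.inner_length < 0 or self.outside_length < 0:
            raise ValueError("line lengths must be non-negative")
        if self.inner_length + self.outside_length <= 0:
            raise ValueError("degenerate line: both extents are zero")
        object.__setattr__(self, "anchor", anchor)
        object.__setattr__(self, "direction", direction / norm)
        object.__setattr__(self, "inner_length", float(self.inner_length))
        object.__setattr__(self, "outside_length", float(self.outside_length))

    @property
    def inner_point(self) -> np.ndarray:
        return self.anchor - self.inner_length * self.direction

    @property
    def outside_point(self) -> np.ndarray:
        return self.anchor + self.outside_length * self.direction


def adjust_line(
    line: LandmarkLine,
    new_anchor=None,
    new_direction=None,
    new_inner_length=None,
    new_outside_length=None,
) -> LandmarkLine:
    """Return a copy of ``line`` with the given fields replaced (the manual
    position/length/direction adjustment step); the direction is
    re-normalized and all invariants re-checked."""
    kwargs = {}
    if new_anchor is not None:
        kwargs["anchor"] = np.asarray(new_anchor, float)
    if new_direction is not None:
        kwargs["direction"] = np.asarray(new_direction, float)
    if new_inner_length is not None:
        kwargs["inner_length"] = float(new_inner_length)
    if new_outside_length is not None:
        kwargs["outside_length"] = float(new_outside_length)
    return replace(line, **kwargs)


@dataclass
class SplintPlan:
    """Ordered up (maxilla) and down (mandible) landmark lines plus
    resampling parameters."""

    up_lines: list
    down_lines: list
    samples_per_span: int = 10
    spline_kind: str = "catmull-rom"

    def validate(self) -> None:
        if len(self.up_lines) != len(self.down_lines):
            raise ValueError("up and down lists must have equal length")
        if len(self.up_lines) < 2:
            raise ValueError("need at least two lines per list")
        if self.samples_per_span < 2:
            raise ValueError("samples_per_span must be >= 2")
        if self.spline_kind not in ("catmull-rom", "linear"):
            raise ValueError(f"unknown spline kind {self.spline_kind!r}")
        for lines in (self.up_lines, self.down_lines):
            anchors = np.array([l.anchor for l in lines])
            chords = np.linalg.norm(np.diff(anchors, axis=0), axis=1)
            if np.any(chords == 0):
                raise ValueError("coincident consecutive anchors")
            # arch ordering: each anchor's nearest other anchor must be a
            # sequence neighbour (monotone arc-length parameterization)
            d = np.linalg.norm(anchors[:, None] - anchors[None, :], axis=2)
            np.fill_diagonal(d, np.inf)
            nearest = np.argmin(d, axis=1)
            if np.any(np.abs(nearest - np.arange(len(lines))) > 1):
                raise ValueError("lines are not ordered along the arch")


# ---------------------------------------------------------------------------
# splines
# ---------------------------------------------------------------------------


def _catmull_rom(points: np.ndarray, samples_per_span: int) -> np.ndarray:
    """Chord-length-parameterized Catmull-Rom through ``points`` (exact
    interpolation), sampled ``samples_per_span`` times per span plus the
    final point.  Ends use reflected virtual control points, so two points
    degenerate to a straight segment."""
    n = len(points)
    chords = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(chords == 0):
        raise ValueError("coincident consecutive points give a zero chord")
    knots = np.concatenate([[0.0], np.cumsum(chords)])
    # virtual endpoints: quadratic extrapolation through the first/last
    # three points keeps end spans curved (plain reflection flattens them);
    # two points degenerate to reflection, i.e. a straight segment
    if n >= 3:
        p_pre = 3 * points[0] - 3 * points[1] + points[2]
        p_post = 3 * points[-1] - 3 * points[-2] + points[-3]
    else:
        p_pre = 2 * points[0] - points[1]
        p_post = 2 * points[-1] - points[-2]
    t_pre = knots[0] - chords[0]
    t_post = knots[-1] + chords[-1]
    ext_pts = np.vstack([p_pre, points, p_post])
    ext_t = np.concatenate([[t_pre], knots, [t_post]])

    out = []
    for span in range(n - 1):
        p0, p1, p2, p3 = ext_pts[span : span + 4]
        t0, t1, t2, t3 = ext_t[span : span + 4]
        local = np.linspace(t1, t2, samples_per_span + 1)
        if span < n - 2:
            local = local[:-1]
        for t in local:
            a1 = _lerp(p0, p1, t0, t1, t)
            a2 = _lerp(p1, p2, t1, t2, t)
            a3 = _lerp(p2, p3, t2, t3, t)
            b1 = _lerp(a1, a2, t0, t2, t)
            b2 = _lerp(a2, a3, t1, t3, t)
            out.append(_lerp(b1, b2, t1, t2, t))
    return np.array(out)


def _lerp(pa, pb, ta, tb, t):
    if tb == ta:
        return pa
    return ((tb - t) * pa + (t - ta) * pb) / (tb - ta)


def _polyline(points: np.ndarray, samples_per_span: int) -> np.ndarray:
    chords = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(chords == 0):
        raise ValueError("coincident consecutive points give a zero chord")
    out = []
    n = len(points)
    for span in range(n - 1):
        w = np.linspace(0.0, 1.0, samples_per_span + 1)
        if span < n - 2:
            w = w[:-1]
        out.append(np.outer(1 - w, points[span]) + np.outer(w, points[span + 1]))
    return np.vstack(out)


def resample_line_series(
    lines, samples_per_span: int, spline_kind: str = "catmull-rom"
):
    """Fit one spline through all inner endpoints and one through all outer
    endpoints, and sample both at ``(len(lines)-1)*samples_per_span + 1``
    parameter values.  Original endpoints are reproduced exactly at the span
    boundaries.

    Returns ``(inner_samples, outer_samples)``, each ``(N, 3)``.
    """
    lines = list(lines)
    if len(lines) < 2:
        raise ValueError("need at least two lines")
    if samples_per_span < 2:
        raise ValueError("samples_per_span must be >= 2")
    inner = np.array([l.inner_point for l in lines])
    outer = np.array([l.outside_point for l in lines])
    fit = {"catmull-rom": _catmull_rom, "linear": _polyline}.get(spline_kind)
    if fit is None:
        raise ValueError(f"unknown spline kind {spline_kind!r}")
    return fit(inner, samples_per_span), fit(outer, samples_per_span)


# ---------------------------------------------------------------------------
# ruled sheets and the closed solid
# ---------------------------------------------------------------------------


def ruled_strip(samples_a: np.ndarray, samples_b: np.ndarray) -> TriangleMesh:
    """Open ruled strip between two equal-length sample polylines:
    2(n-1) triangles, each quad split along the fixed A_i - B_{i+1}
    diagonal."""
    samples_a = np.asarray(samples_a, float)
    samples_b = np.asarray(samples_b, float)
    if len(samples_a) != len(samples_b):
        raise ValueError("sample counts must match")
    n = len(samples_a)
    if n < 2:
        raise ValueError("need at least two samples per rail")
    verts = np.vstack([samples_a, samples_b])
    faces = _strip_faces(np.arange(n), np.arange(n, 2 * n))
    return TriangleMesh(verts, faces)


def _strip_faces(ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    """Faces of a strip between vertex-index rails ia and ib (fixed
    diagonal ia[i] -> ib[i+1])."""
    n = len(ia)
    f = np.empty((2 * (n - 1), 3), dtype=np.int64)
    f[0::2] = np.column_stack([ia[:-1], ib[:-1], ib[1:]])
    f[1::2] = np.column_stack([ia[:-1], ib[1:], ia[1:]])
    return f


def build_initial_splint(plan: SplintPlan) -> TriangleMesh:
    """Assemble the watertight initial-splint solid.

    Six boundary sheets share four spline rails (up-inner, up-outer,
    down-inner, down-outer): the occlusal top and bottom sheets, the lingual
    and buccal walls, and two planar end caps.  All sheets index one shared
    vertex array, so there are no T-junctions; the result is checked
    watertight, scanned for self-intersections, and oriented outward.
    """
    plan.validate()
    u_in, u_out = resample_line_series(
        plan.up_lines, plan.samples_per_span, plan.spline_kind
    )
    d_in, d_out = resample_line_series(
        plan.down_lines, plan.samples_per_span, plan.spline_kind
    )
    n = len(u_in)
    verts = np.vstack([u_in, u_out, d_out, d_in])
    iu_in = np.arange(n)
    iu_out = np.arange(n, 2 * n)
    id_out = np.arange(2 * n, 3 * n)
    id_in = np.arange(3 * n, 4 * n)
    # square-tube cross-section loop: u_in -> u_out -> d_out -> d_in
    rails = [iu_in, iu_out, id_out, id_in]
    faces = [
        _strip_faces(rails[k], rails[(k + 1) % 4]) for k in range(4)
    ]
    # end caps close the tube; windings oppose the adjacent end rungs
    first = [r[0] for r in rails]
    last = [r[-1] for r in rails]
    faces.append(
        np.array(
            [
                [first[0], first[3], first[2]],
                [first[0], first[2], first[1]],
                [last[0], last[1], last[2]],
                [last[0], last[2], last[3]],
            ],
            dtype=np.int64,
        )
    )
    mesh = TriangleMesh(verts, np.vstack(faces))
    if mesh_volume(mesh) < 0:
        mesh = mesh.flipped()
    if not is_watertight(mesh):
        raise RuntimeError("splint base assembly is not watertight")
    if _self_intersects(mesh):
        raise ValueError(
            "splint base self-intersects; adjust line extents or ordering"
        )
    return mesh


def _self_intersects(mesh: TriangleMesh) -> bool:
    """Triangle-triangle intersection scan over non-adjacent face pairs."""
    from .mesh_boolean import CoplanarContactError, _candidate_pairs, _tri_tri_segment

    tri = mesh.triangles
    eps = 1e-12 * max(mesh.bbox_diagonal, 1.0)
    for fa, fb in _candidate_pairs(mesh, mesh, 0.0):
        if fa >= fb:
            continue
        if set(mesh.faces[fa]) & set(mesh.faces[fb]):
            continue  # sharing a vertex or edge is legitimate contact
        try:
            seg = _tri_tri_segment(tri[fa], tri[fb], eps)
        except CoplanarContactError:
            return True
        if seg is not None and np.linalg.norm(seg[1] - seg[0]) > 10 * eps:
            return True
    return False


# ---------------------------------------------------------------------------
# plan file I/O
# ---------------------------------------------------------------------------


def save_plan(plan: SplintPlan, path) -> None:
    doc = {
        "schema": PLAN_SCHEMA,
        "samples_per_span": plan.samples_per_span,
        "spline_kind": plan.spline_kind,
        "up_lines": [_line_doc(l) for l in plan.up_lines],
        "down_lines": [_line_doc(l) for l in plan.down_lines],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def _line_doc(line: LandmarkLine) -> dict:
    return {
        "anchor": list(line.anchor),
        "direction": list(line.direction),
        "inner_length": line.inner_length,
        "outside_length": line.outside_length,
    }


def load_plan(path) -> SplintPlan:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != PLAN_SCHEMA:
        raise ValueError(
            f"unsupported plan schema {doc.get('schema')!r}; expected {PLAN_SCHEMA}"
        )
    def lines(key):
        return [
            LandmarkLine(
                anchor=e["anchor"],
                direction=e["direction"],
                inner_length=e["inner_length"],
                outside_length=e["outside_length"],
            )
            for e in doc[key]
        ]

    plan = SplintPlan(
        up_lines=lines("up_lines"),
        down_lines=lines("down_lines"),
        samples_per_span=int(doc.get("samples_per_span", 10)),
        spline_kind=doc.get("spline_kind", "catmull-rom"),
    )
    plan.validate()
    return plan
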