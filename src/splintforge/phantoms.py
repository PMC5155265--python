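"""Deterministic synthetic geometry: cone frustum, analytic swept model, and
a toy dental arch with undercut teeth.

The frustum is the canonical undercut shape (big end up), and its analytic
swept counterpart — a cylinder at the first-contour radius — is the ground
truth the sweep pipeline is validated against.  The arch phantom stands in
for CT-derived maxilla/mandible meshes: a curved ridge block per jaw
carrying frustum "teeth" whose crowns are wider than their necks, so every
tooth presents an undercut to the occlusal gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_mesh import TriangleMesh, mesh_volume
from .splint_base import LandmarkLine, SplintPlan
from .sweep_undercut import BinaryVolume, marching_cubes

__all__ = [
    "ArchPhantomSpec",
    "make_cone_frustum",
    "make_standard_swept",
    "make_arch_phantom",
    "make_plan_for_arch",
    "crown_tip_points",
]


def make_cone_frustum(
    r_bottom: float, r_top: float, height: float, n_segments: int = 128
) -> TriangleMesh:
    """Watertight cone frustum, axis +z, base disc at z = 0.

    Either radius may be zero (a true cone) but not both.
    """
    if r_bottom < 0 or r_top < 0 or (r_bottom == 0 and r_top == 0):
        raise ValueError("radii must be >= 0 and not both zero")
    if height <= 0:
        raise ValueError("height must be positive")
    if n_segments < 3:
        raise ValueError("need at least 3 segments")
    theta = np.linspace(0.0, 2.0 * np.pi, n_segments, endpoint=False)
    unit = np.column_stack([np.cos(theta), np.sin(theta)])

    verts = []
    faces = []

    def add_ring(radius, z):
        start = len(verts)
        for c in unit:
            verts.append([radius * c[0], radius * c[1], z])
        return np.arange(start, start + n_segments)

    def add_point(x, y, z):
        verts.append([x, y, z])
        return len(verts) - 1

    nxt = lambda idx: np.roll(idx, -1)

    if r_bottom > 0 and r_top > 0:
        rb = add_ring(r_bottom, 0.0)
        rt = add_ring(r_top, height)
        cb = add_point(0.0, 0.0, 0.0)
        ct = add_point(0.0, 0.0, height)
        faces += [[cb, j, i] for i, j in zip(rb, nxt(rb))]  # bottom cap, -z out
        faces += [[ct, i, j] for i, j in zip(rt, nxt(rt))]  # top cap, +z out
        for i in range(n_segments):
            j = (i + 1) % n_segments
            faces.append([rb[i], rb[j], rt[j]])
            faces.append([rb[i], rt[j], rt[i]])
    else:
        # true cone: apex replaces the zero-radius ring
        if r_top == 0:
            ring = add_ring(r_bottom, 0.0)
            apex = add_point(0.0, 0.0, height)
            c = add_point(0.0, 0.0, 0.0)
            faces += [[c, j, i] for i, j in zip(ring, nxt(ring))]
            faces += [[apex, i, j] for i, j in zip(ring, nxt(ring))]
        else:
            ring = add_ring(r_top, height)
            apex = add_point(0.0, 0.0, 0.0)
            c = add_point(0.0, 0.0, height)
            faces += [[c, i, j] for i, j in zip(ring, nxt(ring))]
            faces += [[apex, j, i] for i, j in zip(ring, nxt(ring))]
    mesh = TriangleMesh(np.array(verts, float), np.array(faces, np.int64))
    if mesh_volume(mesh) < 0:
        mesh = mesh.flipped()
    return mesh


def make_standard_swept(
    r_first_contour: float,
    height: float,
    n_segments: int = 128,
    extension: float = 0.0,
) -> TriangleMesh:
    """Analytic ground truth for the swept model of a big-end-up frustum:
    a cylinder at the first-contour radius spanning the frustum height,
    prolonged ``extension`` mm below the base."""
    cyl = make_cone_frustum(
        r_first_contour, r_first_contour, height + extension, n_segments
    )
    return cyl.translated([0.0, 0.0, -extension])


# ---------------------------------------------------------------------------
# dental arch phantom
# ---------------------------------------------------------------------------


@dataclass
class ArchPhantomSpec:
    """Parameters of the toy dental arch (all lengths mm).

    ``tooth_crown_radius > tooth_base_radius`` guarantees each tooth is
    big-end-toward-the-gap, i.e. has an undercut.  ``voxel`` is the implicit
    voxelization resolution of the jaw solids (they are reconstructed by
    marching cubes, like real CT-derived models).
    """

    n_teeth: int = 6
    arch_radius: float = 25.0
    tooth_base_radius: float = 2.2
    tooth_crown_radius: float = 3.0
    tooth_height: float = 7.0
    jaw_gap: float = 4.0
    ridge_width: float = 9.0
    ridge_height: float = 6.0
    arc_span_degrees: float = 150.0
    tooth_embed: float = 1.0
    voxel: float = 0.6
    placement_jitter: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.tooth_crown_radius <= self.tooth_base_radius:
            raise ValueError("crown radius must exceed base radius (undercut)")
        for name in (
            "arch_radius", "tooth_base_radius", "tooth_height", "jaw_gap",
            "ridge_width", "ridge_height", "arc_span_degrees", "voxel",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_teeth < 1:
            raise ValueError("need at least one tooth")

    def tooth_angles(self) -> np.ndarray:
        """Tooth axis angles (radians) along the arch, seeded jitter
        included."""
        half = np.radians(self.arc_span_degrees) / 2.0
        base = np.linspace(np.pi / 2 - half, np.pi / 2 + half, self.n_teeth)
        if self.placement_jitter > 0:
            rng = np.random.default_rng(self.seed)
            base = base + rng.uniform(
                -self.placement_jitter, self.placement_jitter, self.n_teeth
            ) / self.arch_radius
        return base


def make_arch_phantom(spec: ArchPhantomSpec):
    """Build (maxilla, mandible) as watertight marching-cubes solids.

    Each jaw is a curved ridge block along a circular arch with frustum
    teeth whose wide crowns face the occlusal gap.  The mandible is the
    exact z-mirror of the maxilla.  Output is byte-identical for equal spec.
    """
    spec.validate()
    angles = spec.tooth_angles()
    centers = spec.arch_radius * np.column_stack([np.cos(angles), np.sin(angles)])
    if spec.n_teeth > 1:
        min_sep = np.linalg.norm(np.diff(centers, axis=0), axis=1).min()
        if min_sep <= 2 * spec.tooth_crown_radius:
            raise ValueError(
                "teeth overlap: adjacent centers are closer than a crown diameter"
            )

    maxilla = _voxelized_jaw(spec, angles, centers)
    mandible = TriangleMesh(
        maxilla.vertices * np.array([1.0, 1.0, -1.0]), maxilla.faces
    ).flipped()
    return maxilla, mandible


def _voxelized_jaw(spec: ArchPhantomSpec, angles, centers) -> TriangleMesh:
    v = spec.voxel
    r_out = spec.arch_radius + spec.ridge_width / 2 + spec.tooth_crown_radius
    z_crown = spec.jaw_gap / 2.0
    z_base = z_crown + spec.tooth_height
    z_ridge_lo = z_base - spec.tooth_embed
    z_ridge_hi = z_ridge_lo + spec.ridge_height

    xs = np.arange(-r_out - v, r_out + 2 * v, v)
    ys = np.arange(-spec.tooth_crown_radius - v, r_out + 2 * v, v)
    zs = np.arange(z_crown - v, z_ridge_hi + 2 * v, v)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    radial = np.hypot(gx, gy)
    theta = np.arctan2(gy, gx)
    half = np.radians(spec.arc_span_degrees) / 2.0
    pad_angle = (spec.ridge_width / 2.0) / spec.arch_radius
    in_ridge_plan = (np.abs(radial - spec.arch_radius) <= spec.ridge_width / 2) & (
        np.abs(theta - np.pi / 2) <= half + pad_angle
    )

    occupancy = np.zeros((len(xs), len(ys), len(zs)), dtype=np.uint8)
    for k, z in enumerate(zs):
        layer = np.zeros_like(in_ridge_plan)
        if z_ridge_lo <= z <= z_ridge_hi:
            layer |= in_ridge_plan
        if z_crown <= z <= z_base:
            u = (z - z_crown) / spec.tooth_height
            radius = spec.tooth_crown_radius + u * (
                spec.tooth_base_radius - spec.tooth_crown_radius
            )
            for cx, cy in centers:
                layer |= np.hypot(gx - cx, gy - cy) <= radius
        occupancy[:, :, k] = layer
    volume = BinaryVolume(
        origin=np.array([xs[0], ys[0], zs[0]]), spacing=v, values=occupancy
    )
    return marching_cubes(volume)


def make_plan_for_arch(spec: ArchPhantomSpec) -> SplintPlan:
    """Auto-generated landmark plan whose splint base encloses every crown.

    One up/down line pair per tooth, anchored on the arch above/below the
    tooth axis, directed radially (bucco-lingually), wide and deep enough
    that every crown tip lies strictly inside the base solid.
    """
    spec.validate()
    angles = spec.tooth_angles()
    margin = 1.5
    half_width = spec.tooth_crown_radius + margin
    # 0.57 (not a rounder fraction) keeps the occlusal sheets off the jaw
    # models' voxel planes: an exactly grid-aligned sheet would touch the
    # marching-cubes tooth walls tangentially instead of crossing them
    z_face = spec.jaw_gap / 2.0 + 0.57 * spec.tooth_height
    # extra lines past the end teeth, so the planar end caps clear the
    # first/last crowns instead of slicing through their centers
    overhang = (spec.tooth_crown_radius + margin) / spec.arch_radius
    angles = np.concatenate([[angles[0] - overhang], angles, [angles[-1] + overhang]])
    up, down = [], []
    for a in angles:
        radial = np.array([np.cos(a), np.sin(a), 0.0])
        anchor_xy = spec.arch_radius * radial
        up.append(
            LandmarkLine(
                anchor=anchor_xy + [0, 0, z_face],
                direction=radial,
                inner_length=half_width,
                outside_length=half_width,
            )
        )
        down.append(
            LandmarkLine(
                anchor=anchor_xy + [0, 0, -z_face],
                direction=radial,
                inner_length=half_width,
                outside_length=half_width,
            )
        )
    return SplintPlan(up_lines=up, down_lines=down)


def crown_tip_points(spec: ArchPhantomSpec) -> np.ndarray:
    """Crown-face center of every tooth on both jaws (the points a correct
    splint base must enclose)."""
    angles = spec.tooth_angles()
    pts = []
    for a in angles:
        for sign in (+1.0, -1.0):
            pts.append(
                [
                    spec.arch_radius * np.cos(a),
                    spec.arch_radius * np.sin(a),
                    sign * spec.jaw_gap / 2.0,
                ]
            )
    return np.array(pts)
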