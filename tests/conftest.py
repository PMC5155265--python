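"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the package's own geometry kernels:
point-triangle distance is a direct vectorized region-test over *all*
faces, inside/outside is multi-ray crossing parity (Moller-Trumbore), and
solid volumes/areas come from plane-slice voxelization through trimesh +
shapely rather than the signed-distance classification under test.
"""

from __future__ import annotations

import numpy as np
import pytest
import shapely
import trimesh
from shapely.geometry import Polygon

from splintforge import TriangleMesh
from splintforge.phantoms import ArchPhantomSpec, make_arch_phantom, make_plan_for_arch
from splintforge.splint_base import build_initial_splint

# ---------------------------------------------------------------------------
# geometry builders
# ---------------------------------------------------------------------------


def box_mesh(lo, hi) -> TriangleMesh:
    b = trimesh.creation.box(bounds=[list(lo), list(hi)])
    return TriangleMesh(b.vertices, b.faces)


def icosphere_mesh(radius: float, center=(0, 0, 0), subdivisions: int = 3) -> TriangleMesh:
    s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(s.vertices + np.asarray(center, float), s.faces)


@pytest.fixture(scope="session")
def unit_cube() -> TriangleMesh:
    return box_mesh((0, 0, 0), (1, 1, 1))


# small, fast arch phantom shared by the integration-style tests
SMALL_ARCH = ArchPhantomSpec(n_teeth=4, arc_span_degrees=100.0, voxel=0.8)


@pytest.fixture(scope="session")
def arch_spec() -> ArchPhantomSpec:
    return SMALL_ARCH


@pytest.fixture(scope="session")
def arch_jaws(arch_spec):
    return make_arch_phantom(arch_spec)


@pytest.fixture(scope="session")
def arch_plan(arch_spec):
    return make_plan_for_arch(arch_spec)


@pytest.fixture(scope="session")
def arch_base(arch_plan):
    return build_initial_splint(arch_plan)


@pytest.fixture(scope="session")
def arch_splint(arch_base, arch_jaws):
    """Splint blank minus both jaws (the pre-undercut-removal splint)."""
    from splintforge.mesh_boolean import boolean

    maxilla, mandible = arch_jaws
    return boolean(boolean(arch_base, maxilla, "difference"), mandible, "difference")


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_point_triangle_distances(points: np.ndarray, mesh: TriangleMesh) -> np.ndarray:
    """Unsigned distance by exhaustive min over every face (vectorized
    closest-point-on-triangle, no spatial pruning)."""
    t = mesh.triangles
    a, b, c = t[:, 0], t[:, 1], t[:, 2]
    out = np.empty(len(points))
    for i, p in enumerate(points):
        ab, ac, ap = b - a, c - a, p - a
        d1 = np.einsum("ij,ij->i", ab, ap)
        d2 = np.einsum("ij,ij->i", ac, ap)
        bp = p - b
        d3 = np.einsum("ij,ij->i", ab, bp)
        d4 = np.einsum("ij,ij->i", ac, bp)
        cp = p - c
        d5 = np.einsum("ij,ij->i", ab, cp)
        d6 = np.einsum("ij,ij->i", ac, cp)
        va = d3 * d6 - d5 * d4
        vb = d5 * d2 - d1 * d6
        vc = d1 * d4 - d3 * d2
        # interior projection
        denom = va + vb + vc
        denom = np.where(denom == 0, 1.0, denom)
        v = vb / denom
        w = vc / denom
        proj = a + v[:, None] * ab + w[:, None] * ac
        cand = np.linalg.norm(p - proj, axis=1)
        inside = (va >= 0) & (vb >= 0) & (vc >= 0)
        # edge and vertex candidates
        def seg_dist(p0, seg):
            tpar = np.clip(
                np.einsum("ij,ij->i", p0 - seg[0], seg[1] - seg[0])
                / np.maximum(np.einsum("ij,ij->i", seg[1] - seg[0], seg[1] - seg[0]), 1e-300),
                0.0,
                1.0,
            )
            q = seg[0] + tpar[:, None] * (seg[1] - seg[0])
            return np.linalg.norm(p0 - q, axis=1)

        pb = np.broadcast_to(p, a.shape)
        d_edges = np.minimum.reduce(
            [seg_dist(pb, (a, b)), seg_dist(pb, (b, c)), seg_dist(pb, (a, c))]
        )
        out[i] = np.minimum(np.where(inside, cand, np.inf), d_edges).min()
    return out


def rays_inside(points: np.ndarray, mesh: TriangleMesh, n_rays: int = 5,
                seed: int = 12345) -> np.ndarray:
    """Inside test by majority crossing parity over several random rays
    (vectorized Moller-Trumbore)."""
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n_rays, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    t = mesh.triangles
    v0, e1, e2 = t[:, 0], t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]
    votes = np.zeros(len(points), dtype=int)
    for d in dirs:
        h = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, h)
        ok = np.abs(det) > 1e-14
        inv = np.where(ok, 1.0 / np.where(det == 0, 1.0, det), 0.0)
        for i, p in enumerate(points):
            s = p - v0
            u = np.einsum("ij,ij->i", s, h) * inv
            q = np.cross(s, e1)
            v = q @ d * inv
            tt = np.einsum("ij,ij->i", e2, q) * inv
            hit = ok & (u >= 0) & (u <= 1) & (v >= 0) & (u + v <= 1) & (tt > 1e-12)
            votes[i] += int(hit.sum()) % 2
    return votes * 2 > n_rays


def slice_voxelize(mesh: TriangleMesh, spacing: float, bounds=None):
    """Occupancy grid by plane slicing + 2D polygon fill.

    An independent voxelizer: sections through trimesh, ring nesting by
    even-odd XOR, point-in-polygon through shapely.  Returns (origin,
    spacing, occupancy) with voxel centers at origin + index * spacing.
    Pass explicit ``bounds`` to voxelize two solids on a shared grid.
    """
    lo, hi = mesh.bounds if bounds is None else np.asarray(bounds, float)
    xs = np.arange(lo[0] + spacing / 2, hi[0], spacing)
    ys = np.arange(lo[1] + spacing / 2, hi[1], spacing)
    zs = np.arange(lo[2] + spacing / 2, hi[2], spacing)
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    occ = np.zeros((len(xs), len(ys), len(zs)), dtype=bool)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    sections = tm.section_multiplane(
        plane_origin=[0, 0, 0], plane_normal=[0, 0, 1], heights=zs
    )
    for k, path in enumerate(sections):
        if path is None:
            continue
        geom = Polygon()
        to_3d = path.metadata["to_3D"]
        for poly in path.polygons_closed:
            if poly is None:
                continue
            coords = np.asarray(poly.exterior.coords)
            hom = np.column_stack(
                [coords, np.zeros(len(coords)), np.ones(len(coords))]
            )
            world = hom @ to_3d.T
            geom = geom.symmetric_difference(Polygon(world[:, :2]))
        if geom.is_empty:
            continue
        shapely.prepare(geom)
        occ[:, :, k] = shapely.intersects_xy(geom, gx.ravel(), gy.ravel()).reshape(
            len(xs), len(ys)
        )
    origin = np.array([xs[0] if len(xs) else 0.0,
                       ys[0] if len(ys) else 0.0,
                       zs[0] if len(zs) else 0.0])
    return origin, spacing, occ


def voxel_volume(occ: np.ndarray, spacing: float) -> float:
    return float(occ.sum()) * spacing**3


def sample_triangles(mesh: TriangleMesh, n: int, rng) -> np.ndarray:
    """Plain area-weighted surface sampler for the oracle side."""
    t = mesh.triangles
    areas = 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)
    fi = rng.choice(len(areas), size=n, p=areas / areas.sum())
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    tt = t[fi]
    return (
        (1 - r1)[:, None] * tt[:, 0]
        + (r1 * (1 - r2))[:, None] * tt[:, 1]
        + (r1 * r2)[:, None] * tt[:, 2]
    )
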