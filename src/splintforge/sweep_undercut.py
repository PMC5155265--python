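"""Undercut removal by swept-silhouette reconstruction.

A molded part (here: the splint) can only slide off the dentition along a
removal direction ``d`` if the cavity it leaves is free of undercuts —
geometry that widens away from the insertion path, like big-end-up teeth.
The remedy subtracts not the teeth themselves but their *swept silhouette*:
the union of every cross-section the teeth present while translating along
``d``.  Pipeline: slice the model into planar contours orthogonal to ``d``
-> accumulate the contours cumulatively from the far end (the swept
silhouette grows monotonically) -> rasterize into a binary voxel volume ->
morphological closing -> marching-cubes isosurface -> Boolean-subtract from
the splint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
import trimesh as _trimesh
from scipy import ndimage
from shapely.geometry import MultiPolygon, Polygon
from shapely.geometry.polygon import orient
from shapely.ops import unary_union
from skimage import measure

from .core_mesh import TriangleMesh, is_watertight, mesh_volume
from .mesh_boolean import boolean

__all__ = [
    "ContourStack",
    "BinaryVolume",
    "SweepParams",
    "slice_contours",
    "accumulate_sweep",
    "rasterize_stack",
    "close_volume",
    "marching_cubes",
    "sweep_model",
    "eliminate_interference",
]

#: refuse to allocate occupancy grids beyond this many voxels per axis cubed
MAX_VOXELS = 512**3


def direction_frame(direction) -> np.ndarray:
    """Deterministic right-handed orthonormal frame (u, v, d) as columns,
    with d the normalized input direction."""
    d = np.asarray(direction, dtype=float).reshape(3)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("direction must be non-zero")
    d = d / norm
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(d)))] = 1.0
    u = np.cross(helper, d)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return np.column_stack([u, v, d])


@dataclass
class ContourStack:
    """Planar cross-sections orthogonal to the removal direction.

    ``offsets`` are strictly decreasing coordinates along ``direction`` (the
    first slice is the far end in the removal direction); each slice is a
    shapely (Multi)Polygon in the (u, v) coordinates of ``axes``.
    """

    direction: np.ndarray
    spacing: float
    offsets: np.ndarray
    slices: list
    axes: np.ndarray  # columns (u, v, d); local coords = world @ axes

    def validate(self) -> None:
        if len(self.offsets) != len(self.slices):
            raise ValueError("offsets and slices length mismatch")
        if len(self.offsets) > 1 and not np.all(np.diff(self.offsets) < 0):
            raise ValueError("offsets must be strictly decreasing")


@dataclass
class BinaryVolume:
    """Axis-aligned 0/1 occupancy grid with voxel-center convention.

    Local position of voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing``
    (0-based); world position is that vector mapped through ``axes``.  A
    one-voxel zero pad is maintained on all six faces so isosurfaces close.
    """

    origin: np.ndarray
    spacing: float
    values: np.ndarray
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    @property
    def dims(self):
        return self.values.shape

    def is_padded(self) -> bool:
        v = self.values
        if v.size == 0:
            return True
        return not (
            v[0].any() or v[-1].any()
            or v[:, 0].any() or v[:, -1].any()
            or v[:, :, 0].any() or v[:, :, -1].any()
        )


# ---------------------------------------------------------------------------
# slicing
# ---------------------------------------------------------------------------


def slice_contours(mesh: TriangleMesh, direction, spacing: float) -> ContourStack:
    """Cut the model with planes orthogonal to ``direction`` at the given
    spacing, spanning its extent.

    Planes sit at half-spacing offsets inside the extent, so tangent cuts at
    the extreme faces are avoided.  Each slice is the closed plane-mesh
    intersection, counter-clockwise outer rings with holes, in the stack's
    planar frame.  Requires a watertight mesh (open meshes give open loops).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if not is_watertight(mesh):
        raise ValueError("slice_contours requires a watertight mesh")
    axes = direction_frame(direction)
    local = mesh.vertices @ axes  # columns: u, v, d
    z_min, z_max = local[:, 2].min(), local[:, 2].max()
    levels = np.arange(z_max - spacing / 2.0, z_min, -spacing)
    tm = _trimesh.Trimesh(local, mesh.faces, process=False)
    slices = []
    offsets = []
    sections = tm.section_multiplane(
        plane_origin=[0.0, 0.0, 0.0],
        plane_normal=[0.0, 0.0, 1.0],
        heights=levels,
    )
    for z, path in zip(levels, sections):
        geom = Polygon()
        if path is not None:
            to_3d = path.metadata["to_3D"]
            # resolve ring nesting by even-odd XOR: section rings of a
            # watertight mesh never cross, so the symmetric difference of
            # all closed rings is exactly the material region with holes
            for poly in path.polygons_closed:
                if poly is None:
                    continue
                ring = _lift_polygon(Polygon(poly.exterior.coords), to_3d)
                geom = geom.symmetric_difference(ring)
        slices.append(_orient_multi(geom))
        offsets.append(float(z))
    return ContourStack(
        direction=axes[:, 2],
        spacing=float(spacing),
        offsets=np.asarray(offsets),
        slices=slices,
        axes=axes,
    )


def _lift_polygon(poly: Polygon, to_3d: np.ndarray) -> Polygon:
    def ring(coords):
        c = np.asarray(coords)
        hom = np.column_stack([c[:, 0], c[:, 1], np.zeros(len(c)), np.ones(len(c))])
        world = hom @ to_3d.T
        return world[:, :2]  # in-plane frame coords (u, v)

    return Polygon(
        ring(poly.exterior.coords), [ring(r.coords) for r in poly.interiors]
    )


def _orient_multi(geom):
    if geom.is_empty:
        return Polygon()
    if isinstance(geom, Polygon):
        return orient(geom, sign=1.0)
    return MultiPolygon([orient(p, sign=1.0) for p in geom.geoms])


# ---------------------------------------------------------------------------
# sweep accumulation
# ---------------------------------------------------------------------------


def accumulate_sweep(stack: ContourStack) -> ContourStack:
    """Cumulative union of the slices, marching opposite the removal
    direction: output slice i covers everything slices 0..i cover.

    This is the swept silhouette: once a cross-section is occupied at some
    level, it stays occupied at every level below (along -d), so the
    big-end-up cone becomes the constant-radius cylinder of its first
    contour.  A stack whose slices already grow monotonically is a fixpoint.
    """
    stack.validate()
    out = []
    acc = None
    for geom in stack.slices:
        acc = geom if acc is None else unary_union([acc, geom])
        out.append(_orient_multi(acc))
    return ContourStack(
        direction=stack.direction.copy(),
        spacing=stack.spacing,
        offsets=stack.offsets.copy(),
        slices=out,
        axes=stack.axes.copy(),
    )


def extend_stack(stack: ContourStack, extension: float) -> ContourStack:
    """Append copies of the last slice below the near end, prolonging the
    swept solid by ``extension`` mm opposite the removal direction."""
    if extension <= 0:
        return stack
    n_extra = int(np.ceil(extension / stack.spacing))
    extra_offsets = stack.offsets[-1] - stack.spacing * np.arange(1, n_extra + 1)
    return ContourStack(
        direction=stack.direction.copy(),
        spacing=stack.spacing,
        offsets=np.concatenate([stack.offsets, extra_offsets]),
        slices=list(stack.slices) + [stack.slices[-1]] * n_extra,
        axes=stack.axes.copy(),
    )


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def rasterize_stack(stack: ContourStack, spacing: float) -> BinaryVolume:
    """Fill each slice's polygons at voxel centers (boundary-inclusive
    even-odd rule, holes supported) and stack the masks into a padded
    isotropic occupancy grid.

    The grid extent is the stack's bounding box plus a one-voxel zero pad;
    along the sweep axis each voxel layer takes the nearest slice.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    stack.validate()
    boxes = [g.bounds for g in stack.slices if not g.is_empty]
    if not boxes or len(stack.offsets) == 0:
        return BinaryVolume(
            origin=np.zeros(3), spacing=float(spacing),
            values=np.zeros((2, 2, 2), dtype=np.uint8), axes=stack.axes.copy(),
        )
    boxes = np.array(boxes)
    x_min, y_min = boxes[:, 0].min(), boxes[:, 1].min()
    x_max, y_max = boxes[:, 2].max(), boxes[:, 3].max()
    z_lo = float(stack.offsets.min())
    z_hi = float(stack.offsets.max())

    nx = _axis_count(x_min, x_max, spacing)
    ny = _axis_count(y_min, y_max, spacing)
    nz = _axis_count(z_lo, z_hi, spacing)
    if (nx + 2) * (ny + 2) * (nz + 2) > MAX_VOXELS:
        raise ValueError(
            f"occupancy grid {nx + 2}x{ny + 2}x{nz + 2} exceeds the "
            f"{round(MAX_VOXELS ** (1 / 3))}^3 voxel guard; "
            "increase voxel spacing"
        )
    xs = x_min + spacing * np.arange(nx)
    ys = y_min + spacing * np.arange(ny)
    zs = z_lo + spacing * np.arange(nz)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")

    values = np.zeros((nx + 2, ny + 2, nz + 2), dtype=np.uint8)
    masks: dict[int, np.ndarray] = {}
    # offsets are descending; map each voxel layer to its nearest slice
    desc = stack.offsets
    for k, z in enumerate(zs):
        s = int(np.argmin(np.abs(desc - z)))
        if s not in masks:
            geom = stack.slices[s]
            if geom.is_empty:
                masks[s] = np.zeros((nx, ny), dtype=bool)
            else:
                shapely.prepare(geom)
                masks[s] = shapely.intersects_xy(
                    geom, gx.ravel(), gy.ravel()
                ).reshape(nx, ny)
        values[1:-1, 1:-1, k + 1] = masks[s]
    origin = np.array([x_min - spacing, y_min - spacing, z_lo - spacing])
    return BinaryVolume(
        origin=origin, spacing=float(spacing), values=values, axes=stack.axes.copy()
    )


def _axis_count(lo: float, hi: float, spacing: float) -> int:
    return int(np.floor((hi - lo) / spacing + 0.5 + 1e-9)) + 1


# ---------------------------------------------------------------------------
# morphology and reconstruction
# ---------------------------------------------------------------------------


def close_volume(volume: BinaryVolume, iterations: int) -> BinaryVolume:
    """Morphological closing (dilate then erode) with the 6-connected
    structuring element, ``iterations`` times; zero padding is preserved by
    padding out before the dilation can reach the boundary."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0 or not volume.values.any():
        return BinaryVolume(
            volume.origin.copy(), volume.spacing, volume.values.copy(),
            volume.axes.copy(),
        )
    pad = iterations
    padded = np.pad(volume.values.astype(bool), pad)
    structure = ndimage.generate_binary_structure(3, 1)
    closed = ndimage.binary_closing(padded, structure=structure, iterations=iterations)
    closed = closed[pad:-pad, pad:-pad, pad:-pad]
    out = BinaryVolume(
        volume.origin.copy(), volume.spacing,
        closed.astype(np.uint8), volume.axes.copy(),
    )
    if not out.is_padded():  # closing cannot grow, but be defensive
        out.values = np.pad(out.values, 1)
        out.origin = out.origin - out.spacing
    return out


def marching_cubes(volume: BinaryVolume, iso: float = 0.5) -> TriangleMesh:
    """Closed outward-oriented isosurface of the occupancy grid at ``iso``,
    vertices on voxel-edge crossings (linear interpolation of the 0/1
    field).  The volume must be zero-padded; an all-zero volume gives an
    empty mesh."""
    if not volume.is_padded():
        raise ValueError("volume boundary is occupied; marching cubes needs padding")
    if not volume.values.any():
        return TriangleMesh.empty()
    s = volume.spacing
    verts, faces, _, _ = measure.marching_cubes(
        volume.values.astype(np.float32), level=iso, spacing=(s, s, s)
    )
    local = verts + volume.origin
    mesh = TriangleMesh(local @ volume.axes.T, faces)
    if mesh_volume(mesh) < 0:
        mesh = mesh.flipped()
    return mesh


# ---------------------------------------------------------------------------
# the full sweep and the interference elimination
# ---------------------------------------------------------------------------


@dataclass
class SweepParams:
    """Tunable parameters of the undercut-removal sweep (all mm).

    ``extension`` prolongs the swept solid opposite the removal direction so
    the cavity opens fully; ``None`` means the teeth model's own extent
    along -d.  ``clearance`` buffers the silhouette outward before
    rasterization; ``None`` means one voxel, which absorbs half-voxel
    marching-cubes jitter and guarantees removability of the result.
    """

    slice_spacing: float = 0.5
    voxel_spacing: float = 0.25
    closing_iterations: int = 1
    extension: float | None = None
    clearance: float | None = None


def sweep_model(
    mesh: TriangleMesh,
    removal_direction,
    slice_spacing: float = 0.5,
    voxel_spacing: float = 0.25,
    closing_iterations: int = 1,
    extension: float = 0.0,
    clearance: float = 0.0,
) -> TriangleMesh:
    """Swept-silhouette ("temporary") model of ``mesh`` along the removal
    direction: slice -> accumulate -> extend -> rasterize -> close ->
    marching cubes.  The result is watertight and covers every cross-section
    the model presents while translating along the direction."""
    stack = slice_contours(mesh, removal_direction, slice_spacing)
    acc = accumulate_sweep(stack)
    acc = extend_stack(acc, extension)
    if clearance > 0:
        acc = ContourStack(
            direction=acc.direction,
            spacing=acc.spacing,
            offsets=acc.offsets,
            slices=[
                _orient_multi(g.buffer(clearance)) if not g.is_empty else g
                for g in acc.slices
            ],
            axes=acc.axes,
        )
    volume = rasterize_stack(acc, voxel_spacing)
    volume = close_volume(volume, closing_iterations)
    swept = marching_cubes(volume)
    if not swept.is_empty and not is_watertight(swept):
        raise RuntimeError("swept reconstruction is not watertight")
    return swept


def eliminate_interference(
    splint: TriangleMesh,
    teeth: TriangleMesh,
    removal_direction,
    params: SweepParams | None = None,
) -> TriangleMesh:
    """Subtract the swept silhouette of ``teeth`` along the removal
    direction from ``splint``, so the result can slide off without
    collision."""
    if params is None:
        params = SweepParams()
    if splint.is_empty:
        return splint.copy()
    d = np.asarray(removal_direction, float)
    d = d / np.linalg.norm(d)
    if params.extension is None:
        proj = teeth.vertices @ d
        extension = float(proj.max() - proj.min())
    else:
        extension = params.extension
    clearance = (
        params.voxel_spacing if params.clearance is None else params.clearance
    )
    swept = sweep_model(
        teeth,
        d,
        slice_spacing=params.slice_spacing,
        voxel_spacing=params.voxel_spacing,
        closing_iterations=params.closing_iterations,
        extension=extension,
        clearance=clearance,
    )
    if swept.is_empty:
        return splint.copy()
    return boolean(splint, swept, "difference")
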