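"""Swept-silhouette undercut removal: slicing, accumulation, rasterization,
morphology, marching cubes, and the composed pipeline."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from conftest import box_mesh, icosphere_mesh
from splintforge import TriangleMesh
from splintforge.core_mesh import is_watertight, mean_surface_distance, mesh_volume
from splintforge.phantoms import make_cone_frustum, make_standard_swept
from splintforge.sweep_undercut import (
    BinaryVolume,
    ContourStack,
    accumulate_sweep,
    close_volume,
    marching_cubes,
    rasterize_stack,
    slice_contours,
    sweep_model,
)


def square_stack(side=10.0, offsets=(0.0,), spacing=0.5):
    half = side / 2
    square = Polygon([(-half, -half), (half, -half), (half, half), (-half, half)])
    return ContourStack(
        direction=np.array([0.0, 0.0, 1.0]),
        spacing=spacing,
        offsets=np.asarray(offsets, float),
        slices=[square] * len(offsets),
        axes=np.eye(3),
    )


class TestSliceContours:
    def test_frustum_radius_profile(self):
        frustum = make_cone_frustum(8, 12, 20, 128)
        stack = slice_contours(frustum, [0, 0, 1], 0.5)
        assert np.all(np.diff(stack.offsets) < 0)
        for k in range(0, len(stack.offsets), 7):
            z = stack.offsets[k]
            r_measured = np.sqrt(stack.slices[k].area / np.pi)
            assert r_measured == pytest.approx(8 + 4 * z / 20, abs=0.05)

    def test_cube_slices_identical_squares(self):
        cube = box_mesh((0, 0, 0), (4, 4, 4))
        stack = slice_contours(cube, [0, 0, 1], 0.5)
        for geom in stack.slices:
            assert geom.area == pytest.approx(16.0, abs=1e-9)

    def test_oblique_direction(self):
        cube = box_mesh((0, 0, 0), (4, 4, 4))
        stack = slice_contours(cube, [1, 1, 1], 0.5)
        # cross-section of a cube along its body diagonal starts and ends
        # in triangles; just check closed non-empty polygons and ordering
        assert np.all(np.diff(stack.offsets) < 0)
        assert any(not g.is_empty for g in stack.slices)

    def test_open_mesh_rejected(self):
        cube = box_mesh((0, 0, 0), (1, 1, 1))
        broken = TriangleMesh(cube.vertices, cube.faces[:-1])
        with pytest.raises(ValueError):
            slice_contours(broken, [0, 0, 1], 0.5)


class TestAccumulate:
    def test_big_end_up_frustum_becomes_first_disc(self):
        """Removal toward the big end turns every slice into the first
        (largest) contour — the swept model is the constant-radius
        silhouette."""
        frustum = make_cone_frustum(8, 12, 20, 128)
        acc = accumulate_sweep(slice_contours(frustum, [0, 0, 1], 0.5))
        first_area = acc.slices[0].area
        for geom in acc.slices:
            assert geom.area == pytest.approx(first_area, rel=1e-9)

    def test_monotone_stack_is_fixpoint(self):
        frustum = make_cone_frustum(12, 8, 20, 128)  # big end down
        stack = slice_contours(frustum, [0, 0, 1], 0.5)
        acc = accumulate_sweep(stack)
        for raw, out in zip(stack.slices, acc.slices):
            assert out.area == pytest.approx(raw.area, rel=1e-9)

    def test_matches_cumulative_or_oracle(self):
        """Rasterized accumulation equals a brute-force cumulative OR along
        the axis on a random 20x20x20 occupancy stack."""
        rng = np.random.default_rng(42)
        grid = 20
        spacing = 1.0
        slices = []
        for _ in range(grid):
            cells = rng.random((grid, grid)) < 0.12
            polys = [
                Polygon(
                    [(i, j), (i + 1, j), (i + 1, j + 1), (i, j + 1)]
                ).buffer(-0.2)
                for i, j in zip(*np.nonzero(cells))
            ]
            from shapely.ops import unary_union

            slices.append(unary_union(polys) if polys else Polygon())
        offsets = np.arange(grid)[::-1].astype(float)
        stack = ContourStack(
            direction=np.array([0.0, 0.0, 1.0]),
            spacing=spacing,
            offsets=offsets,
            slices=slices,
            axes=np.eye(3),
        )
        acc = accumulate_sweep(stack)
        # rasterize each slice at cell centers and compare to cumulative OR
        import shapely

        gx, gy = np.meshgrid(
            np.arange(grid) + 0.5, np.arange(grid) + 0.5, indexing="ij"
        )
        raw_masks = np.array(
            [
                shapely.intersects_xy(g, gx.ravel(), gy.ravel()).reshape(grid, grid)
                for g in slices
            ]
        )
        acc_masks = np.array(
            [
                shapely.intersects_xy(g, gx.ravel(), gy.ravel()).reshape(grid, grid)
                for g in acc.slices
            ]
        )
        expected = np.logical_or.accumulate(raw_masks, axis=0)
        assert np.array_equal(acc_masks, expected)


class TestRasterize:
    def test_square_inclusive_voxel_count(self):
        volume = rasterize_stack(square_stack(side=10.0, spacing=0.5), 0.5)
        # interior slab (padding stripped): inclusive voxel centers
        core = volume.values[1:-1, 1:-1, 1:-1]
        assert core.shape[:2] == (21, 21)
        assert core.sum() == 21 * 21
        assert volume.is_padded()

    def test_empty_stack_all_zero(self):
        stack = ContourStack(
            direction=np.array([0.0, 0.0, 1.0]), spacing=0.5,
            offsets=np.array([0.0]), slices=[Polygon()], axes=np.eye(3),
        )
        volume = rasterize_stack(stack, 0.5)
        assert volume.values.sum() == 0

    def test_disc_area_from_voxel_count(self):
        r = 6.0
        spacing = r / 20
        disc = Polygon(
            (r * np.cos(t), r * np.sin(t))
            for t in np.linspace(0, 2 * np.pi, 720)
        )
        stack = ContourStack(
            direction=np.array([0.0, 0.0, 1.0]), spacing=spacing,
            offsets=np.array([0.0]), slices=[disc], axes=np.eye(3),
        )
        volume = rasterize_stack(stack, spacing)
        count = volume.values[:, :, 1:-1].sum()
        assert count * spacing**2 == pytest.approx(np.pi * r * r, rel=0.03)


class TestCloseVolume:
    def test_empty_unchanged(self):
        volume = BinaryVolume(np.zeros(3), 1.0, np.zeros((4, 4, 4), np.uint8))
        assert close_volume(volume, 2).values.sum() == 0

    def test_solid_block_unchanged(self):
        values = np.zeros((7, 7, 7), np.uint8)
        values[1:-1, 1:-1, 1:-1] = 1
        volume = BinaryVolume(np.zeros(3), 1.0, values)
        closed = close_volume(volume, 1)
        assert np.array_equal(closed.values, values)

    def test_interior_hole_filled(self):
        values = np.zeros((7, 7, 7), np.uint8)
        values[1:-1, 1:-1, 1:-1] = 1
        values[3, 3, 3] = 0
        volume = BinaryVolume(np.zeros(3), 1.0, values)
        closed = close_volume(volume, 1)
        assert closed.values[3, 3, 3] == 1
        assert closed.values.sum() == 5**3

    def test_zero_iterations_identity(self):
        values = (np.random.default_rng(0).random((6, 6, 6)) < 0.2).astype(np.uint8)
        values[0] = values[-1] = 0
        values[:, 0] = values[:, -1] = 0
        values[:, :, 0] = values[:, :, -1] = 0
        volume = BinaryVolume(np.zeros(3), 1.0, values)
        assert np.array_equal(close_volume(volume, 0).values, values)


class TestMarchingCubes:
    def test_all_zero_gives_empty_mesh(self):
        volume = BinaryVolume(np.zeros(3), 1.0, np.zeros((4, 4, 4), np.uint8))
        assert marching_cubes(volume).is_empty

    def test_single_voxel_closed_and_bounded(self):
        values = np.zeros((3, 3, 3), np.uint8)
        values[1, 1, 1] = 1
        spacing = 0.5
        mesh = marching_cubes(BinaryVolume(np.zeros(3), spacing, values))
        assert is_watertight(mesh)
        assert 0 < mesh_volume(mesh) <= 8 * spacing**3

    def test_unpadded_volume_rejected(self):
        values = np.ones((3, 3, 3), np.uint8)
        with pytest.raises(ValueError):
            marching_cubes(BinaryVolume(np.zeros(3), 1.0, values))

    def test_rasterized_sphere_within_one_voxel(self):
        """A sphere rasterized at 0.25 mm and reconstructed by marching
        cubes stays within one voxel of the analytic sphere on average."""
        r, spacing = 10.0, 0.25
        sphere = icosphere_mesh(r, subdivisions=4)
        stack = slice_contours(sphere, [0, 0, 1], spacing)
        volume = rasterize_stack(stack, spacing)
        mesh = marching_cubes(volume)
        assert is_watertight(mesh)
        d = mean_surface_distance(mesh, sphere, 10_000, seed=0)
        assert d <= spacing


class TestSweepModel:
    def test_frustum_approximates_standard_cylinder(self):
        frustum = make_cone_frustum(8, 12, 20, 128)
        swept = sweep_model(frustum, [0, 0, 1], 0.5, 0.25, 1, 0.0)
        standard = make_standard_swept(12, 20, 128)
        assert is_watertight(swept)
        d = mean_surface_distance(swept, standard, 10_000, seed=0)
        assert d <= 0.365

    def test_sphere_sweeps_to_capsule_silhouette(self):
        """Sweeping a sphere yields a cylinder capped by the leading
        hemisphere; the volume matches the analytic silhouette within 3%."""
        r = 6.0
        sphere = icosphere_mesh(r, center=(0, 0, r), subdivisions=4)
        swept = sweep_model(sphere, [0, 0, 1], 0.4, 0.25, 1, 0.0)
        # hemisphere (top) + cylinder of radius r over the lower extent
        analytic = 2 * np.pi * r**3 / 3 + np.pi * r**2 * r
        assert mesh_volume(swept) == pytest.approx(analytic, rel=0.03)

    def test_cylinder_is_sweep_fixpoint(self):
        cylinder = make_cone_frustum(6, 6, 15, 128)
        swept = sweep_model(cylinder, [0, 0, 1], 0.5, 0.25, 1, 0.0)
        d = mean_surface_distance(swept, cylinder, 10_000, seed=0)
        assert d <= 2 * 0.25

    def test_monotone_columns_after_sweep(self):
        """Every voxel column of the accumulated volume along the removal
        direction is 0...0 1...1."""
        frustum = make_cone_frustum(5, 9, 12, 64)
        stack = accumulate_sweep(slice_contours(frustum, [0, 0, 1], 0.5))
        volume = rasterize_stack(stack, 0.5)
        v = volume.values
        diffs = np.diff(v.astype(int), axis=2)
        # along +z (the removal direction) occupancy may only switch on
        # once: 0->1 transitions at most one per column after reversal
        starts = (diffs == 1).sum(axis=2)
        ends = (diffs == -1).sum(axis=2)
        assert starts.max() <= 1 and ends.max() <= 1

    def test_sweep_only_adds_material(self):
        frustum = make_cone_frustum(8, 12, 20, 64)
        swept = sweep_model(frustum, [0, 0, 1], 0.5, 0.25, 1, 0.0)
        voxel_tol = 0.25 * frustum.area  # one voxel of surface skin
        assert mesh_volume(swept) >= mesh_volume(frustum) - voxel_tol

    def test_sweep_idempotent_within_voxel(self):
        frustum = make_cone_frustum(6, 9, 12, 64)
        once = sweep_model(frustum, [0, 0, 1], 0.5, 0.3, 1, 0.0)
        twice = sweep_model(once, [0, 0, 1], 0.5, 0.3, 1, 0.0)
        assert mean_surface_distance(once, twice, 8000, seed=1) <= 0.3

    def test_resolution_convergence(self):
        """Halving the slice and voxel spacing together brings the swept
        frustum closer to the analytic standard model (the error floor is
        set by the slicing discretization, so both must refine)."""
        frustum = make_cone_frustum(8, 12, 20, 128)
        standard = make_standard_swept(12, 20, 128)
        errors = [
            mean_surface_distance(
                sweep_model(frustum, [0, 0, 1], s, h, 1, 0.0),
                standard, 10_000, seed=0,
            )
            for s, h in ((1.0, 0.5), (0.5, 0.25))
        ]
        assert errors[1] < errors[0]

    def test_voxel_guard(self):
        frustum = make_cone_frustum(8, 12, 20, 32)
        with pytest.raises(ValueError, match="voxel"):
            sweep_model(frustum, [0, 0, 1], 0.5, 0.001, 1, 0.0)
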