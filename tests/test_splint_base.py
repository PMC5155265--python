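"""Landmark lines, spline resampling, ruled strips, and the closed base."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splintforge.core_mesh import is_watertight, mesh_volume
from splintforge.splint_base import (
    LandmarkLine,
    SplintPlan,
    adjust_line,
    build_initial_splint,
    load_plan,
    resample_line_series,
    ruled_strip,
    save_plan,
)


def vertical_line(x, y=0.0, z=0.0, half=4.0):
    return LandmarkLine(anchor=[x, y, z], direction=[0, 1, 0],
                        inner_length=half, outside_length=half)


def box_plan(width=8.0, height=6.0, length=40.0, n=5, samples=10):
    xs = np.linspace(0, length, n)
    up = [vertical_line(x, z=height, half=width / 2) for x in xs]
    down = [vertical_line(x, z=0.0, half=width / 2) for x in xs]
    return SplintPlan(up, down, samples_per_span=samples)


class TestLandmarkLine:
    def test_direction_normalized_and_endpoints(self):
        line = LandmarkLine([1, 2, 3], [0, 0, 2], inner_length=2, outside_length=3)
        assert np.allclose(line.direction, [0, 0, 1])
        assert np.allclose(line.inner_point, [1, 2, 1])
        assert np.allclose(line.outside_point, [1, 2, 6])

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            LandmarkLine([0, 0, 0], [0, 0, 0], 1, 1)
        with pytest.raises(ValueError):
            LandmarkLine([0, 0, 0], [1, 0, 0], 0, 0)
        with pytest.raises(ValueError):
            LandmarkLine([0, 0, 0], [1, 0, 0], -1, 2)

    def test_adjust_identity(self):
        line = vertical_line(1.0)
        same = adjust_line(line)
        assert np.allclose(same.anchor, line.anchor)
        assert np.allclose(same.direction, line.direction)
        assert same.inner_length == line.inner_length
        assert same.outside_length == line.outside_length

    def test_adjust_outside_length_moves_endpoint_linearly(self):
        line = vertical_line(0.0, half=3.0)
        doubled = adjust_line(line, new_outside_length=6.0)
        moved = doubled.outside_point - line.outside_point
        assert np.allclose(moved, 3.0 * line.direction)

    def test_adjust_renormalizes_direction(self):
        line = adjust_line(vertical_line(0.0), new_direction=(0, 0, 2))
        assert np.allclose(line.direction, [0, 0, 1])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        direction=st.tuples(
            *([st.floats(-10, 10, allow_nan=False)] * 3)
        ).filter(lambda d: sum(x * x for x in d) > 1e-6),
        inner=st.floats(0, 20, allow_nan=False),
        outer=st.floats(0.1, 20, allow_nan=False),
    )
    def test_line_invariants_hold_for_any_input(self, direction, inner, outer):
        """Direction always stored unit-norm; endpoints collinear with the
        anchor along it."""
        line = LandmarkLine([1.0, -2.0, 3.0], direction, inner, outer)
        assert np.linalg.norm(line.direction) == pytest.approx(1.0, abs=1e-9)
        span = line.outside_point - line.inner_point
        residual = span - (span @ line.direction) * line.direction
        assert np.linalg.norm(residual) <= 1e-9 * (1 + np.linalg.norm(span))

    def test_adjust_invalid_rejected(self):
        with pytest.raises(ValueError):
            adjust_line(vertical_line(0.0), new_direction=(0, 0, 0))
        with pytest.raises(ValueError):
            adjust_line(vertical_line(0.0), new_inner_length=-1)


class TestResampling:
    def test_two_lines_give_straight_segments(self):
        lines = [vertical_line(0.0), vertical_line(10.0)]
        inner, outer = resample_line_series(lines, samples_per_span=5)
        assert len(inner) == 6
        # every sample is an affine combination of the two endpoints
        for series, p0, p1 in (
            (inner, lines[0].inner_point, lines[1].inner_point),
            (outer, lines[0].outside_point, lines[1].outside_point),
        ):
            t = (series[:, 0] - p0[0]) / (p1[0] - p0[0])
            expected = np.outer(1 - t, p0) + np.outer(t, p1)
            assert np.abs(series - expected).max() <= 1e-9

    def test_collinear_points_stay_collinear(self):
        lines = [vertical_line(x) for x in np.linspace(0, 30, 6)]
        inner, outer = resample_line_series(lines, samples_per_span=7)
        for series in (inner, outer):
            spans = series - series[0]
            axis = spans[-1] / np.linalg.norm(spans[-1])
            offsets = spans - np.outer(spans @ axis, axis)
            assert np.abs(offsets).max() <= 1e-9

    def test_knots_interpolated_exactly(self):
        rng = np.random.default_rng(2)
        anchors = np.cumsum(rng.uniform(1, 3, size=(6, 3)), axis=0)
        lines = [
            LandmarkLine(a, [0, 0, 1], inner_length=1, outside_length=2)
            for a in anchors
        ]
        inner, outer = resample_line_series(lines, samples_per_span=4)
        for k, line in enumerate(lines):
            assert np.abs(inner[4 * k] - line.inner_point).max() <= 1e-9
            assert np.abs(outer[4 * k] - line.outside_point).max() <= 1e-9

    def test_circle_arc_accuracy(self):
        """Eight landmarks on a 30 mm circle resample to within 0.25 mm of
        the circle (checked against the analytic radius)."""
        theta = np.linspace(np.pi / 6, np.pi - np.pi / 6, 8)  # arch-like arc
        lines = [
            LandmarkLine(
                [30 * np.cos(t), 30 * np.sin(t), 0.0],
                [np.cos(t), np.sin(t), 0.0],
                inner_length=0.0,
                outside_length=1.0,
            )
            for t in theta
        ]
        inner, _ = resample_line_series(lines, samples_per_span=40)
        radii = np.linalg.norm(inner[:, :2], axis=1)
        assert np.abs(radii - 30.0).max() <= 0.25

    def test_zero_chord_rejected(self):
        lines = [vertical_line(0.0), vertical_line(0.0), vertical_line(5.0)]
        with pytest.raises(ValueError):
            resample_line_series(lines, samples_per_span=4)


class TestRuledStrip:
    def test_parallel_rectangle_area(self):
        n = 9
        a = np.column_stack([np.linspace(0, 12, n), np.zeros(n), np.zeros(n)])
        b = a + [0.0, 3.0, 0.0]
        strip = ruled_strip(a, b)
        assert len(strip.faces) == 2 * (n - 1)
        assert strip.area == pytest.approx(36.0, abs=1e-9)

    def test_two_samples_two_triangles(self):
        strip = ruled_strip([[0, 0, 0], [1, 0, 0]], [[0, 1, 0], [1, 1, 0]])
        assert len(strip.faces) == 2

    def test_skew_strip_area_matches_quadrature(self):
        """Strip between skew segments matches quadrature of the ruling's
        area element.

        The strip's full-height triangles split each quad along a fixed
        diagonal, so its area converges to the quadrature of
        (|(B-A) x A'| + |(B-A) x B'|) / 2 over the ruling parameter — and,
        for a mild twist, stays close to the smooth bilinear-patch area."""
        p0, p1 = np.array([0.0, 0, 0]), np.array([10.0, 0, 0])
        q0, q1 = np.array([0.0, 4, 3]), np.array([10.0, 6, -2])
        n = 400
        t = np.linspace(0, 1, n)
        a = np.outer(1 - t, p0) + np.outer(t, p1)
        b = np.outer(1 - t, q0) + np.outer(t, q1)
        strip = ruled_strip(a, b)
        # 200-point quadrature of the triangulated ruling's area element
        tq = np.linspace(0, 1, 200)
        rung = np.outer(1 - tq, q0 - p0) + np.outer(tq, q1 - p1)
        da = np.linalg.norm(np.cross(rung, p1 - p0), axis=-1)
        db = np.linalg.norm(np.cross(rung, q1 - q0), axis=-1)
        limit = 0.5 * (np.trapezoid(da, tq) + np.trapezoid(db, tq))
        assert strip.area == pytest.approx(limit, rel=1e-3)
        # and the smooth patch area bounds it from below, within a few %
        tt, ss = np.meshgrid(tq, tq)
        x_t = (1 - ss)[..., None] * (p1 - p0) + ss[..., None] * (q1 - q0)
        x_s = (1 - tt)[..., None] * (q0 - p0) + tt[..., None] * (q1 - p1)
        smooth = np.linalg.norm(np.cross(x_t, x_s), axis=-1).mean()
        assert smooth <= strip.area <= smooth * 1.05

    def test_mismatched_counts_rejected(self):
        with pytest.raises(ValueError):
            ruled_strip(np.zeros((4, 3)), np.zeros((5, 3)))


class TestBuildInitialSplint:
    def test_box_volume(self):
        plan = box_plan(width=8, height=6, length=40)
        mesh = build_initial_splint(plan)
        assert is_watertight(mesh)
        assert mesh_volume(mesh) == pytest.approx(8 * 6 * 40, rel=1e-3)

    def test_strip_count_law(self):
        plan = box_plan(n=5, samples=10)
        mesh = build_initial_splint(plan)
        n_samples = (5 - 1) * 10 + 1
        assert len(mesh.faces) == 4 * 2 * (n_samples - 1) + 4

    def test_arch_plan_watertight_sphere_topology(self, arch_plan):
        mesh = build_initial_splint(arch_plan)
        assert is_watertight(mesh)
        assert mesh.euler_characteristic() == 2
        assert mesh_volume(mesh) > 0

    def test_reversed_lists_give_congruent_solid(self, arch_plan):
        mesh = build_initial_splint(arch_plan)
        reversed_plan = SplintPlan(
            arch_plan.up_lines[::-1],
            arch_plan.down_lines[::-1],
            arch_plan.samples_per_span,
            arch_plan.spline_kind,
        )
        rev = build_initial_splint(reversed_plan)
        assert mesh_volume(rev) == pytest.approx(mesh_volume(mesh), rel=1e-9)

    def test_boundary_vertices_on_rails(self):
        plan = box_plan()
        inner, outer = resample_line_series(
            plan.up_lines, plan.samples_per_span, plan.spline_kind
        )
        mesh = build_initial_splint(plan)
        # every up-rail sample must appear among the mesh vertices
        for rail in (inner, outer):
            d = np.abs(mesh.vertices[None, :, :] - rail[:, None, :]).sum(axis=2).min(axis=1)
            assert d.max() <= 1e-9

    def test_refinement_converges(self, arch_plan):
        """Doubling the sampling density changes the volume by less than the
        previous refinement step (Cauchy-style convergence)."""
        volumes = []
        for samples in (4, 8, 16):
            plan = SplintPlan(
                arch_plan.up_lines, arch_plan.down_lines, samples, arch_plan.spline_kind
            )
            volumes.append(mesh_volume(build_initial_splint(plan)))
        assert abs(volumes[2] - volumes[1]) < abs(volumes[1] - volumes[0])

    def test_mismatched_lists_rejected(self):
        plan = box_plan()
        bad = SplintPlan(plan.up_lines, plan.down_lines[:-1])
        with pytest.raises(ValueError):
            build_initial_splint(bad)

    def test_unordered_lines_rejected(self):
        plan = box_plan()
        shuffled = SplintPlan(
            [plan.up_lines[i] for i in (0, 2, 1, 3, 4)], plan.down_lines
        )
        with pytest.raises(ValueError):
            shuffled.validate()


class TestPlanIO:
    def test_roundtrip(self, arch_plan, tmp_path):
        path = tmp_path / "plan.json"
        save_plan(arch_plan, path)
        back = load_plan(path)
        assert len(back.up_lines) == len(arch_plan.up_lines)
        for a, b in zip(back.up_lines, arch_plan.up_lines):
            assert np.allclose(a.anchor, b.anchor)
            assert np.allclose(a.direction, b.direction)

    def test_unknown_schema_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"schema": "other/9", "up_lines": [], "down_lines": []}')
        with pytest.raises(ValueError, match="schema"):
            load_plan(path)
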