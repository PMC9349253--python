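"""Geometry: plane construction, virtual plane, tilt, feasibility, mirror."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sectplan import (
    BlockFrame,
    CuttingPlane,
    DegenerateGeometryError,
    GeometryError,
    TargetCenter,
    check_feasibility,
    cutting_forward_distance,
    fit_plane,
    mirror_x,
    plane_through_targets,
    tilt_angle,
    virtual_plane,
)
from sectplan.exceptions import ConfigError

FRAME = BlockFrame(10000.0, 10000.0, 8000.0)


def targets(*coords):
    return [TargetCenter(f"T{i}", *c) for i, c in enumerate(coords, 1)]


class TestPlaneThroughTargets:
    def test_contains_all_three_reference_targets(self, three_target_block):
        ts = three_target_block.centers
        plane = plane_through_targets(*ts)
        for t in ts:
            assert abs(float(plane.signed_distance(t.point))) < 1e-6
        assert abs(np.linalg.norm(plane.normal) - 1.0) < 1e-9
        assert plane.normal[2] > 0

    def test_equal_depth_targets_give_horizontal_plane(self):
        ts = targets((1000, 1000, 5000), (8000, 2000, 5000), (4000, 7000, 5000))
        plane = plane_through_targets(*ts)
        assert np.allclose(plane.normal, [0, 0, 1], atol=1e-12)
        assert tilt_angle(plane) == pytest.approx(0.0, abs=1e-9)

    def test_collinear_targets_rejected_with_names(self):
        ts = targets((0, 0, 0), (1000, 0, 0), (2000, 0, 0))
        with pytest.raises(DegenerateGeometryError, match="T1.*T2.*T3"):
            plane_through_targets(*ts)

    def test_coincident_targets_rejected(self):
        ts = targets((1000, 1000, 1000), (1000, 1000, 1000), (2000, 3000, 4000))
        with pytest.raises(DegenerateGeometryError):
            plane_through_targets(*ts)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(
        st.tuples(st.floats(0, 10000), st.floats(0, 10000), st.floats(0, 8000)),
        min_size=3, max_size=3, unique=True))
    def test_containment_property(self, coords):
        ts = targets(*coords)
        try:
            plane = plane_through_targets(*ts)
        except DegenerateGeometryError:
            return
        for t in ts:
            assert abs(float(plane.signed_distance(t.point))) < 1e-6


class TestFitPlane:
    def test_three_targets_match_exact_construction(self, three_target_block):
        ts = three_target_block.centers
        exact = plane_through_targets(*ts)
        fitted = fit_plane(ts)
        assert np.linalg.norm(fitted.normal - exact.normal) < 1e-9

    def test_recovers_plane_from_four_exact_points(self):
        # points constructed exactly on the plane with normal ~(1,2,5)/norm
        n = np.array([1.0, 2.0, 5.0])
        n = n / np.linalg.norm(n)
        d = 4000.0 * n[2]  # plane through (0,0,4000)-ish region

        def z_of(x, y):
            return (d - n[0] * x - n[1] * y) / n[2]

        pts = [(x, y, z_of(x, y)) for x, y in
               [(1000, 1000), (6000, 1500), (2000, 7000), (7000, 6000)]]
        fitted = fit_plane(targets(*pts))
        assert np.linalg.norm(fitted.normal - n) < 1e-9
        for p in pts:
            assert abs(float(fitted.signed_distance(np.array(p)))) < 1e-6

    def test_symmetric_noise_beats_brute_force_candidates(self):
        # 100 points on a known plane with alternating +/-eps z-noise; the
        # orthogonal-LS fit must score at least as well as any candidate
        # normal on a brute-force grid, and stay close to the truth.
        rng = np.random.default_rng(42)
        n_true = np.array([0.1, -0.15, 1.0])
        n_true = n_true / np.linalg.norm(n_true)
        eps = 5.0
        xy = rng.uniform(500, 9500, size=(100, 2))
        z = (4000.0 * n_true[2] - xy @ n_true[:2]) / n_true[2]
        z = z + eps * np.where(np.arange(100) % 2 == 0, 1.0, -1.0)
        pts = np.column_stack([xy, z])
        fitted = fit_plane(targets(*map(tuple, pts)))

        def sse(normal):
            normal = normal / np.linalg.norm(normal)
            c = pts.mean(axis=0)
            return float((((pts - c) @ normal) ** 2).sum())

        best_grid = min(
            sse(np.array([math.sin(t) * math.cos(p), math.sin(t) * math.sin(p),
                          math.cos(t)]))
            for t in np.linspace(0.0, 0.5, 41)
            for p in np.linspace(0, 2 * math.pi, 73)
        )
        assert sse(fitted.normal) <= best_grid + 1e-9
        angle = math.degrees(math.acos(min(abs(float(fitted.normal @ n_true)), 1.0)))
        assert angle < 0.1  # eps=5 µm noise over a 9 mm spread

    def test_collinear_cloud_rejected(self):
        pts = [(i * 1000.0, i * 500.0, i * 250.0) for i in range(5)]
        with pytest.raises(DegenerateGeometryError):
            fit_plane(targets(*pts))


class TestVirtualPlane:
    def test_reference_tip_heights(self, three_target_block):
        # depths 4000/5000/6000, deepest Blue: heights 2*6000 - z
        _, guide = virtual_plane(three_target_block.centers)
        assert guide.tip_height("Red") == pytest.approx(8000.0)
        assert guide.tip_height("Green") == pytest.approx(7000.0)
        assert guide.tip_height("Blue") == pytest.approx(6000.0)

    def test_three_planes_parallel_with_equal_spacing(self, three_target_block):
        ts = three_target_block.centers
        expected = plane_through_targets(*ts)
        virt, guide = virtual_plane(ts)
        assert virt.is_parallel(expected)
        # tips lie on the virtual plane
        for tip in guide.tip_points:
            assert abs(float(virt.signed_distance(tip))) < 1e-6
        z_b = max(t.z for t in ts)
        # expected -> suppositional -> virtual: equal spacing Z_b along the feed
        supp = expected.translated(-z_b)
        gap1 = float(expected.signed_distance(supp.point))
        gap2 = float(supp.signed_distance(virt.point))
        assert gap1 == pytest.approx(gap2, abs=1e-9)

    def test_equal_depth_targets_all_heights_equal_depth(self):
        ts = targets((1000, 1000, 5000), (8000, 2000, 5000), (4000, 7000, 5000))
        virt, guide = virtual_plane(ts)
        assert all(n.tip_height == pytest.approx(5000.0) for n in guide.needles)
        assert tilt_angle(virt) == pytest.approx(0.0, abs=1e-9)

    def test_deepest_tie_is_order_invariant(self):
        a = targets((1000, 1000, 6000), (8000, 2000, 6000), (4000, 7000, 3000))
        b = [a[1], a[0], a[2]]
        _, ga = virtual_plane(a)
        _, gb = virtual_plane(b)
        heights_a = {n.name: n.tip_height for n in ga.needles}
        heights_b = {n.name: n.tip_height for n in gb.needles}
        assert heights_a == heights_b
        assert min(heights_a.values()) == pytest.approx(6000.0)

    def test_unique_deepest_needle_attains_minimum_height_z_b(self, three_target_block):
        _, guide = virtual_plane(three_target_block.centers)
        heights = [n.tip_height for n in guide.needles]
        assert min(heights) == pytest.approx(6000.0)  # = Z_b
        assert heights.count(min(heights)) == 1


class TestTiltAngle:
    def test_horizontal_plane_has_zero_tilt(self):
        plane = CuttingPlane(np.array([0.0, 0.0, 1.0]), np.zeros(3))
        assert tilt_angle(plane) == pytest.approx(0.0)

    def test_constructed_ten_degree_plane(self):
        dz = math.tan(math.radians(10.0)) * 10000.0
        ts = targets((0, 0, 1000), (10000, 0, 1000), (0, 10000, 1000 + dz))
        assert tilt_angle(plane_through_targets(*ts)) == pytest.approx(10.0, abs=1e-9)

    def test_matches_cross_product_oracle(self, three_target_block):
        ts = three_target_block.centers
        plane = plane_through_targets(*ts)
        # independent oracle: raw cross product, no CuttingPlane machinery
        n = np.cross(ts[1].point - ts[0].point, ts[2].point - ts[0].point)
        oracle = math.degrees(math.acos(abs(n[2]) / np.linalg.norm(n)))
        assert tilt_angle(plane) == pytest.approx(oracle, abs=1e-9)

    @settings(derandomize=True, max_examples=40)
    @given(st.floats(0.0, 2 * math.pi))
    def test_invariant_under_rotation_about_z_and_normal_flip(self, theta):
        ts = [t.point for t in targets((2000, 1000, 4000), (8000, 3000, 5000),
                                       (5000, 7000, 6000))]
        rot = np.array([
            [math.cos(theta), -math.sin(theta), 0],
            [math.sin(theta), math.cos(theta), 0],
            [0, 0, 1],
        ])
        base = plane_through_targets(
            *targets(*[tuple(p) for p in ts]))
        rotated = CuttingPlane(rot @ base.normal, rot @ base.point)
        flipped = CuttingPlane(-base.normal, base.point)
        assert tilt_angle(rotated) == pytest.approx(tilt_angle(base), abs=1e-9)
        assert tilt_angle(flipped) == pytest.approx(tilt_angle(base), abs=1e-9)


class TestFeasibility:
    def test_flat_plane_feasible_with_zero_wedge(self):
        plane = CuttingPlane(np.array([0.0, 0.0, 1.0]), np.zeros(3))
        v = check_feasibility(plane)
        assert v.feasible and v.wedge_deg == 0.0

    def test_29_degree_tilt_needs_9_degree_wedge(self):
        # an 81°-to-bottom pre-trim corresponds to a 9° inclined face
        n = np.array([math.sin(math.radians(29.0)), 0.0,
                      math.cos(math.radians(29.0))])
        v = check_feasibility(CuttingPlane(n, np.zeros(3)), capacity_deg=20.0)
        assert not v.feasible
        assert v.wedge_deg == pytest.approx(9.0, abs=1e-9)

    def test_boundary_tilt_exactly_at_capacity_is_feasible(self):
        n = np.array([math.sin(math.radians(20.0)), 0.0,
                      math.cos(math.radians(20.0))])
        v = check_feasibility(CuttingPlane(n, np.zeros(3)), capacity_deg=20.0)
        assert v.feasible

    @pytest.mark.parametrize("capacity", [0.0, -5.0, 90.0, 120.0])
    def test_capacity_out_of_range_rejected(self, capacity):
        plane = CuttingPlane(np.array([0.0, 0.0, 1.0]), np.zeros(3))
        with pytest.raises(ConfigError):
            check_feasibility(plane, capacity_deg=capacity)


class TestMirror:
    @settings(derandomize=True, max_examples=50)
    @given(st.tuples(st.floats(-10000, 10000), st.floats(0, 10000),
                     st.floats(0, 8000)))
    def test_involution(self, p):
        pt = np.array(p)
        assert np.allclose(mirror_x(mirror_x(pt, FRAME), FRAME), pt)

    def test_point_on_mirror_axis_unchanged(self):
        pt = np.array([0.0, 4000.0, 2000.0])
        assert np.allclose(mirror_x(pt, FRAME), pt)

    def test_hand_computed_oracle_points(self):
        # origin at the plate end (0, 0): x -> -x, y and z preserved
        cases = [
            ((2000.0, 1000.0, 4000.0), (-2000.0, 1000.0, 4000.0)),
            ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0)),
            ((5000.0, 7000.0, 6000.0), (-5000.0, 7000.0, 6000.0)),
            ((9999.0, 1.0, 8000.0), (-9999.0, 1.0, 8000.0)),
            ((123.0, 456.0, 789.0), (-123.0, 456.0, 789.0)),
        ]
        for inp, expected in cases:
            assert np.allclose(mirror_x(np.array(inp), FRAME), expected)

    def test_preserves_z_and_pairwise_distances(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 8000, size=(6, 3))
        mirrored = np.array([mirror_x(p, FRAME) for p in pts])
        assert np.allclose(mirrored[:, 2], pts[:, 2])
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d1 = np.linalg.norm(mirrored[:, None] - mirrored[None, :], axis=-1)
        assert np.allclose(d0, d1)

    def test_mirroring_a_plane_preserves_tilt(self, three_target_block):
        plane = plane_through_targets(*three_target_block.centers)
        mirrored = mirror_x(plane, FRAME)
        assert tilt_angle(mirrored) == pytest.approx(tilt_angle(plane))
        assert np.allclose(mirror_x(mirrored, FRAME).normal, plane.normal)


class TestCuttingForwardDistance:
    def test_perpendicular_case(self):
        start = CuttingPlane(np.array([0.0, 0.0, 1.0]), np.zeros(3))
        target = start.translated(6000.0)
        adv = cutting_forward_distance(target, (5000.0, 5000.0), FRAME, start)
        assert adv == pytest.approx(6000.0)

    def test_tilted_case_divides_by_cos_tilt(self):
        # same 6000 µm perpendicular offset, 10° tilt -> 6000/cos(10°)
        a = math.radians(10.0)
        n = np.array([math.sin(a), 0.0, math.cos(a)])
        start = CuttingPlane(n, np.zeros(3))
        target = CuttingPlane(n, 6000.0 * n)  # perpendicular offset 6000
        mx, my = 5000.0, 5000.0
        adv = cutting_forward_distance(target, (mx, my), FRAME, start)
        assert adv == pytest.approx(6000.0 / math.cos(a))
        # and the blade plane indeed reaches the target plane at the mark
        lifted = np.array([mx, my, target.z_at(mx, my)])
        assert abs(float(start.translated(adv).signed_distance(lifted))) < 1e-6

    def test_full_pipeline_hits_all_targets(self, three_target_block):
        ts = three_target_block.centers
        expected = plane_through_targets(*ts)
        virt, _ = virtual_plane(ts)
        deepest = max(ts, key=lambda t: t.z)
        adv = cutting_forward_distance(
            expected, deepest.footprint, three_target_block.frame, start=virt
        )
        blade = virt.translated(adv)
        for t in ts:
            assert abs(float(blade.signed_distance(t.point))) < 3.5

    def test_non_parallel_planes_rejected(self):
        start = CuttingPlane(np.array([0.0, 0.0, 1.0]), np.zeros(3))
        target = CuttingPlane(np.array([0.1, 0.0, 1.0]), np.zeros(3))
        with pytest.raises(GeometryError, match="parallel"):
            cutting_forward_distance(target, (5000.0, 5000.0), FRAME, start)

    def test_mark_behind_start_rejected(self):
        start = CuttingPlane(np.array([0.0, 0.0, 1.0]),
                             np.array([0.0, 0.0, 7000.0]))
        target = CuttingPlane(np.array([0.0, 0.0, 1.0]), np.zeros(3))
        with pytest.raises(GeometryError, match="behind"):
            cutting_forward_distance(target, (5000.0, 5000.0), FRAME, start)

    def test_mark_outside_bottom_face_rejected(self):
        start = CuttingPlane(np.array([0.0, 0.0, 1.0]), np.zeros(3))
        target = start.translated(5000.0)
        with pytest.raises(GeometryError, match="outside"):
            cutting_forward_distance(target, (50000.0, 5000.0), FRAME, start)
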