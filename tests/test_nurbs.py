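"""Core NURBS machinery: evaluation, interpolation, refinement, networks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thvforge import nurbs
from thvforge.nurbs import (
    CurveNetwork,
    IntersectionNotFound,
    KnotVector,
    NetworkError,
    NurbsCurve,
    NurbsSurface,
    arc_through_points,
    curve_length,
    element_count,
    eval_curve,
    gordon_surface,
    h_refine_uniform,
    interpolate_curve,
    intersect_curves,
    loft,
    open_uniform_knots,
    reflect,
    rotate_z,
    split_curve,
    translate,
)


def quarter_circle():
    return arc_through_points(
        [1, 0, 0], [np.cos(np.pi / 4), np.sin(np.pi / 4), 0], [0, 1, 0]
    )


def wiggly_curve():
    pts = np.array(
        [[0, 0, 0], [1, 0.8, 0.2], [2, -0.3, 0.7], [3.2, 0.5, 1.4], [4, 0, 2], [5, 1, 2.5]]
    )
    return interpolate_curve(pts)


class TestKnots:
    @pytest.mark.parametrize(
        "n_ctrl, degree, n_spans",
        [(4, 3, 1), (31, 3, 28), (5, 3, 2), (22, 3, 19)],
    )
    def test_open_uniform_span_count(self, n_ctrl, degree, n_spans):
        kv = open_uniform_knots(n_ctrl, degree)
        assert kv.n_elements() == n_spans
        assert np.all(kv.values[: degree + 1] == 0) and np.all(
            kv.values[-(degree + 1):] == 1
        )

    def test_single_bezier_and_midpoint(self):
        assert open_uniform_knots(4, 3).values.tolist() == [0, 0, 0, 0, 1, 1, 1, 1]
        assert open_uniform_knots(5, 3).values[4] == 0.5

    def test_too_few_control_points_rejected(self):
        with pytest.raises(ValueError):
            open_uniform_knots(3, 3)

    def test_unclamped_vector_rejected(self):
        with pytest.raises(ValueError):
            KnotVector(np.array([0, 0, 0, 0.5, 1, 1, 1, 1.5]), 3)


class TestEvaluation:
    def test_clamped_endpoint_interpolation(self):
        c = wiggly_curve()
        assert np.allclose(eval_curve(c, 0.0), c.control_points[0] * 0 + c.evaluate(0))
        np.testing.assert_allclose(c.evaluate(0.0), [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(c.evaluate(1.0), [5, 1, 2.5], atol=1e-12)

    def test_straight_control_polygon_stays_on_line(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, -1.0, 0.5])
        ctrl = np.array([a + t * (b - a) for t in [0, 0.3, 0.7, 1.0]])
        c = NurbsCurve(ctrl, open_uniform_knots(4, 3))
        for u in np.linspace(0, 1, 17):
            p = c.evaluate(u)
            t = np.dot(p - a, b - a) / np.dot(b - a, b - a)
            np.testing.assert_allclose(p, a + t * (b - a), atol=1e-12)

    def test_rational_arc_midpoint_on_circle(self):
        arc = quarter_circle()
        p = arc.evaluate(0.5)
        assert abs(np.linalg.norm(p) - 1.0) < 1e-12

    def test_out_of_range_parameter_rejected(self):
        with pytest.raises(ValueError):
            wiggly_curve().evaluate(1.5)


class TestInterpolation:
    def test_collinear_points_give_straight_chord(self):
        pts = np.array([[0, 0, 0], [0, 0, 0.5], [0, 0, 1.2], [0, 0, 2.0]])
        c = interpolate_curve(pts)
        assert abs(curve_length(c) - 2.0) < 1e-9

    def test_greville_round_trip(self):
        c = wiggly_curve()
        grev = c.knots.greville_abscissae()
        samples = c.evaluate(grev)
        c2 = interpolate_curve(samples, params=grev, knots=c.knots)
        ts = np.linspace(0, 1, 200)
        assert np.abs(c2.evaluate(ts) - c.evaluate(ts)).max() < 1e-9

    def test_two_points_with_tangents_is_hermite(self):
        a, b = np.zeros(3), np.array([1.0, 0, 0])
        d0, d1 = np.array([0, 3.0, 0]), np.array([0, -3.0, 0])
        c = interpolate_curve([a, b], end_tangents=(d0, d1))
        np.testing.assert_allclose(c.evaluate(0.0), a, atol=1e-12)
        np.testing.assert_allclose(c.evaluate(1.0), b, atol=1e-12)
        np.testing.assert_allclose(c.derivative(0.0), d0, atol=1e-9)
        np.testing.assert_allclose(c.derivative(1.0), d1, atol=1e-9)

    def test_interpolation_residual_bound(self, rng):
        pts = np.cumsum(rng.normal(size=(9, 3)), axis=0)
        c = interpolate_curve(pts)
        params = nurbs._chord_params(pts)
        resid = np.linalg.norm(c.evaluate(params) - pts, axis=1).max()
        assert resid < 1e-10

    def test_coincident_consecutive_points_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            interpolate_curve(np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0], [2, 0, 0]]))


class TestRefinement:
    @pytest.mark.parametrize("levels", [0, 1, 2, 3])
    def test_span_doubling_and_geometry_preserved(self, levels):
        c = wiggly_curve()
        r = h_refine_uniform(c, levels)
        assert element_count(r) == element_count(c) * 2**levels
        ts = np.linspace(0, 1, 200)
        assert np.abs(r.evaluate(ts) - c.evaluate(ts)).max() <= 1e-12

    def test_level_zero_is_identity(self):
        c = wiggly_curve()
        assert h_refine_uniform(c, 0) is c

    def test_negative_levels_rejected(self):
        with pytest.raises(ValueError):
            h_refine_uniform(wiggly_curve(), -1)

    def test_rational_refinement_preserves_circle(self):
        arc = h_refine_uniform(quarter_circle(), 2)
        ts = np.linspace(0, 1, 100)
        assert np.abs(np.linalg.norm(arc.evaluate(ts), axis=1) - 1).max() < 1e-12


class TestTransforms:
    def test_quarter_turn_point(self):
        p = rotate_z(np.array([13.15, 0.0, 0.0]), 90.0)
        np.testing.assert_allclose(p, [0, 13.15, 0], atol=1e-12)

    def test_full_turn_identity(self):
        c = wiggly_curve()
        r = rotate_z(c, 360.0)
        assert np.abs(r.control_points - c.control_points).max() < 1e-12

    @given(
        a=st.floats(-180, 180),
        b=st.floats(-180, 180),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rotation_composition(self, a, b):
        p = np.array([1.3, -0.4, 2.0])
        lhs = rotate_z(rotate_z(p, a), b)
        rhs = rotate_z(p, a + b)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_reflection_involution_and_azimuth(self):
        c = wiggly_curve()
        assert np.abs(reflect(reflect(c, 37.0), 37.0).control_points - c.control_points).max() < 1e-12
        p = np.array([np.cos(np.radians(12)), np.sin(np.radians(12)), 1.0])
        q = reflect(p, 0.0)
        assert abs(np.degrees(np.arctan2(q[1], q[0])) + 12.0) < 1e-12

    def test_point_on_mirror_plane_fixed(self):
        p = np.array([np.cos(np.radians(60)), np.sin(np.radians(60)), 2.0]) * 3
        np.testing.assert_allclose(reflect(p, 60.0), p, atol=1e-12)

    def test_translate_round_trip_and_length_invariance(self):
        c = wiggly_curve()
        v = np.array([1.0, -2.0, 0.5])
        back = translate(translate(c, v), -v)
        assert np.abs(back.control_points - c.control_points).max() < 1e-14
        assert translate(c, [0, 0, 0]).control_points == pytest.approx(c.control_points)
        assert abs(curve_length(translate(c, v)) - curve_length(c)) < 1e-9
        assert abs(curve_length(rotate_z(c, 123.0)) - curve_length(c)) < 1e-9

    def test_transform_evaluation_equivariance(self):
        c = wiggly_curve()
        ts = np.linspace(0, 1, 50)
        for op in (lambda g: rotate_z(g, 77.0), lambda g: reflect(g, 30.0), lambda g: translate(g, [1, 2, 3])):
            lhs = op(c).evaluate(ts)
            rhs = np.array([op(p) for p in c.evaluate(ts)])
            assert np.abs(lhs - rhs).max() < 1e-12


class TestSplitJoin:
    def test_split_straight_segment_at_midpoint(self):
        pts = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2], [0, 0, 3.0]])
        c = interpolate_curve(pts)
        left, right = split_curve(c, 0.5)
        assert abs(curve_length(left) - 1.5) < 1e-9
        assert abs(curve_length(right) - 1.5) < 1e-9

    def test_split_reproduces_geometry(self):
        c = wiggly_curve()
        u0 = 0.37
        left, right = split_curve(c, u0)
        ts = np.linspace(0, 1, 150)
        assert np.abs(left.evaluate(ts) - c.evaluate(ts * u0)).max() < 1e-12
        assert np.abs(right.evaluate(ts) - c.evaluate(u0 + ts * (1 - u0))).max() < 1e-12

    def test_split_arc_sweeps_sum(self):
        arc = quarter_circle()
        a, b = split_curve(arc, 0.3)
        assert abs(curve_length(a) + curve_length(b) - np.pi / 2) < 1e-9

    @pytest.mark.parametrize("u", [0.0, 1.0, -0.2, 1.1])
    def test_split_at_or_beyond_ends_rejected(self, u):
        with pytest.raises(ValueError):
            split_curve(wiggly_curve(), u)

    def test_join_shares_endpoint(self):
        c = wiggly_curve()
        left, right = split_curve(c, 0.4)
        j = nurbs.join_curves(left, right)
        ts = np.linspace(0, 1, 100)
        d = [np.linalg.norm(c.evaluate(t) - j.evaluate(t2)) for t, t2 in zip([0, 1], [0, 1])]
        assert max(d) < 1e-12
        with pytest.raises(ValueError, match="gap"):
            nurbs.join_curves(left, translate(right, [1, 0, 0]))


class TestIntersection:
    def test_crossing_straight_segments(self):
        a = interpolate_curve(np.array([[-1, -1, 0], [0, 0, 0], [1, 1, 0], [2, 2, 0]]))
        b = interpolate_curve(np.array([[-1, 1, 0], [0, 0, 0], [1, -1, 0], [2, -2, 0]]))
        u, v, pt, resid = intersect_curves(a, b)
        assert resid < 1e-10
        np.testing.assert_allclose(pt, [0, 0, 0], atol=1e-8)

    def test_coplanar_arcs_cross(self):
        def arc(center, deg0, deg1):
            th = np.radians([deg0, (deg0 + deg1) / 2, deg1])
            return arc_through_points(
                *[[center[0] + np.cos(t), center[1] + np.sin(t), 0] for t in th]
            )

        a1 = arc((0, 0), 0, 90)
        a2 = arc((1.2, 0), 90, 180)
        # circles of radius 1 centered 1.2 apart cross at (0.6, +/-0.8)
        u, v, pt, resid = intersect_curves(a1, a2, tol=1e-6)
        assert resid < 1e-8
        np.testing.assert_allclose(pt, [0.6, 0.8, 0.0], atol=1e-8)

    def test_parallel_disjoint_lines_not_found(self):
        a = interpolate_curve(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]))
        b = translate(a, [0, 1, 0])
        with pytest.raises(IntersectionNotFound):
            intersect_curves(a, b, tol=1e-3)


class TestLoft:
    def test_two_parallel_lines_make_planar_strip(self):
        a = interpolate_curve(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0.0]]))
        b = translate(a, [0, 2, 0])
        s = loft([a, b])
        g = s.evaluate_grid(np.linspace(0, 1, 9), np.linspace(0, 1, 9))
        assert np.abs(g[..., 2]).max() < 1e-12

    def test_sections_interpolated_as_iso_lines(self):
        def ring(r, z):
            th = np.linspace(0, 2 * np.pi / 3, 9)
            return interpolate_curve(
                np.column_stack([r * np.cos(th), r * np.sin(th), np.full(9, z)])
            )

        cs = [ring(1, 0), ring(1.4, 1), ring(2, 2)]
        s = loft(cs, v_params=np.array([0.0, 0.5, 1.0]))
        ts = np.linspace(0, 1, 60)
        for c, v in zip(cs, [0.0, 0.5, 1.0]):
            iso = s.evaluate_grid(ts, [v])[:, 0, :]
            assert np.abs(iso - c.evaluate(ts)).max() < 1e-10

    def test_fewer_than_two_curves_rejected(self):
        with pytest.raises(ValueError):
            loft([wiggly_curve()])

    def test_identical_curves_warn_degenerate(self):
        c = wiggly_curve()
        with pytest.warns(UserWarning, match="degenerate"):
            loft([c, c])


class TestGordon:
    @staticmethod
    def planar_network():
        xs, ys = np.linspace(0, 3, 4), np.linspace(0, 2, 5)
        u_curves = [
            nurbs.interpolate_curve(np.column_stack([xs, np.full(4, y), np.zeros(4)]))
            for y in ys
        ]
        v_curves = [
            nurbs.interpolate_curve(
                np.column_stack([np.full(4, x), np.linspace(0, 2, 4), np.zeros(4)])
            )
            for x in xs
        ]
        return u_curves, v_curves

    def test_planar_network_gives_planar_surface(self):
        u_curves, v_curves = self.planar_network()
        net = CurveNetwork.build(u_curves, v_curves)
        s = gordon_surface(net)
        g = s.evaluate_grid(np.linspace(0, 1, 15), np.linspace(0, 1, 15))
        assert np.abs(g[..., 2]).max() < 1e-9

    def test_bicubic_patch_round_trip(self, rng):
        ctrl = np.stack(
            np.meshgrid(np.arange(4.0), np.arange(4.0), indexing="ij"), axis=-1
        )
        ctrl = np.concatenate([ctrl, rng.normal(0, 0.4, size=(4, 4, 1))], axis=2)
        kv = open_uniform_knots(4, 3)
        patch = NurbsSurface(ctrl, kv, kv)
        st4 = np.array([0.0, 0.3, 0.7, 1.0])
        u_curves = [patch.iso_curve("v", v) for v in st4]
        v_curves = [patch.iso_curve("u", u) for u in st4]
        net = CurveNetwork.build(u_curves, v_curves)
        g = gordon_surface(net)
        ts = np.linspace(0, 1, 25)
        err = np.abs(g.evaluate_grid(ts, ts) - patch.evaluate_grid(ts, ts)).max()
        assert err < 1e-8

    def test_cylinder_network(self):
        r = 13.0
        th = np.radians(np.linspace(0, 120, 61))
        rings = [
            nurbs.interpolate_curve(
                np.column_stack([r * np.cos(th), r * np.sin(th), np.full(len(th), z)])
            )
            for z in (0.0, 10.0)
        ]
        lines = [
            nurbs.interpolate_curve(
                np.column_stack(
                    [
                        np.full(4, r * np.cos(t)),
                        np.full(4, r * np.sin(t)),
                        np.linspace(0, 10, 4),
                    ]
                )
            )
            for t in th[::2]
        ]
        net = CurveNetwork.build(rings, lines)
        s = gordon_surface(net)
        g = s.evaluate_grid(np.linspace(0, 1, 30), np.linspace(0, 1, 10))
        assert np.abs(np.hypot(g[..., 0], g[..., 1]) - r).max() < 1e-6

    def test_non_intersecting_pair_reported(self):
        u_curves, v_curves = self.planar_network()
        v_curves[1] = translate(v_curves[1], [0, 0, 5.0])
        with pytest.raises(NetworkError, match="non-intersecting"):
            CurveNetwork.build(u_curves, v_curves)

    def test_loft_consistency_when_v_curves_are_iso_lines(self):
        u_curves, _ = self.planar_network()
        s_loft = loft(u_curves, v_params=np.linspace(0, 1, 5))
        v_curves = [s_loft.iso_curve("u", u) for u in [0.0, 0.4, 0.8, 1.0]]
        net = CurveNetwork.build(u_curves, v_curves)
        g = gordon_surface(net)
        ts = np.linspace(0, 1, 20)
        assert np.abs(g.evaluate_grid(ts, ts) - s_loft.evaluate_grid(ts, ts)).max() < 1e-10


class TestMeasures:
    def test_straight_segment_length(self):
        c = interpolate_curve(np.array([[0, 0, 0], [0, 0, 0.5], [0, 0, 1.5], [0, 0, 2.0]]))
        assert abs(curve_length(c) - 2.0) < 1e-10

    def test_quarter_circle_length(self):
        assert abs(curve_length(quarter_circle()) - np.pi / 2) < 1e-8

    def test_element_count_single_bezier(self):
        c = NurbsCurve(np.zeros((4, 3)) + np.arange(4)[:, None], open_uniform_knots(4, 3))
        assert element_count(c) == 1

    def test_arc_through_points_circumcircle(self):
        center = np.array([1.0, -2.0, 0.5])
        r = 3.3
        angles = [0.2, 0.9, 1.7]
        p = [center + r * np.array([np.cos(a), np.sin(a), 0]) for a in angles]
        arc = arc_through_points(*p)
        ts = np.linspace(0, 1, 50)
        d = np.linalg.norm(arc.evaluate(ts) - center, axis=1)
        assert np.abs(d - r).max() < 1e-9

    def test_arc_collinear_points_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            arc_through_points([0, 0, 0], [1, 0, 0], [2, 0, 0])


class TestJsonExchange:
    def test_curve_round_trip_bit_exact(self):
        c = quarter_circle()
        c2 = NurbsCurve.from_dict(c.to_dict())
        assert np.array_equal(c.control_points, c2.control_points)
        assert np.array_equal(c.weights, c2.weights)
        assert np.array_equal(c.knots.values, c2.knots.values)

    def test_surface_round_trip_bit_exact(self):
        kv = open_uniform_knots(4, 3)
        s = NurbsSurface(np.random.default_rng(0).normal(size=(4, 4, 3)), kv, kv)
        s2 = NurbsSurface.from_dict(s.to_dict())
        assert np.array_equal(s.control_points, s2.control_points)
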