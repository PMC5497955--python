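"""Geometry primitives against independent oracles and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from valvedim import geometry
from conftest import ellipse_points


def random_star_polygon(rng, n=12, radius=100.0):
    """Simple polygon, star-shaped about the origin (angle-sorted radii).

    Angular gaps are kept below pi so the origin stays interior, which
    the origin-fan triangulation oracle requires.
    """
    while True:
        angles = np.sort(rng.uniform(0, 2 * np.pi, n))
        gaps = np.diff(np.concatenate([angles, [angles[0] + 2 * np.pi]]))
        if gaps.max() < 0.9 * np.pi:
            break
    radii = rng.uniform(0.3 * radius, radius, n)
    return np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])


def fan_triangulation_area(pts):
    """Independent oracle: unsigned triangle areas fanned from the origin,
    valid for polygons star-shaped about the origin."""
    total = 0.0
    for i in range(len(pts)):
        v1, v2 = pts[i], pts[(i + 1) % len(pts)]
        total += 0.5 * abs(v1[0] * v2[1] - v1[1] * v2[0])
    return total


class TestPolygonArea:
    @pytest.mark.parametrize("pts,expected", [
        ([(0, 0), (1, 0), (1, 1), (0, 1)], 1.0),
        ([(0, 0), (4, 0), (0, 3)], 6.0),
    ])
    def test_known_shapes(self, pts, expected):
        assert geometry.polygon_area(np.array(pts, float)) == pytest.approx(expected)

    def test_matches_fan_triangulation_on_random_polygons(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            poly = random_star_polygon(rng, n=int(rng.integers(5, 20)))
            assert geometry.polygon_area(poly) == pytest.approx(
                fan_triangulation_area(poly), rel=1e-9)

    def test_vertex_order_invariant(self):
        rng = np.random.default_rng(1)
        poly = random_star_polygon(rng)
        assert geometry.polygon_area(poly) == pytest.approx(
            geometry.polygon_area(poly[::-1]), rel=1e-12)

    def test_too_few_points_error(self):
        with pytest.raises(ValueError, match=">= 3"):
            geometry.polygon_area(np.array([[0, 0], [1, 1]], float))

    def test_collinear_error(self):
        with pytest.raises(ValueError, match="zero area"):
            geometry.polygon_area(np.array([[0, 0], [1, 1], [2, 2]], float))

    def test_self_intersection_warns(self):
        bowtie = np.array([[0, 0], [2, 2], [2, 0], [0, 2.5]], float)
        with pytest.warns(UserWarning, match="self-intersecting"):
            geometry.polygon_area(bowtie)


def _point_to_ellipse_dist(p, xc, yc, a, b, theta):
    ct, s = math.cos(-theta), math.sin(-theta)
    x = ct * (p[0] - xc) - s * (p[1] - yc)
    y = s * (p[0] - xc) + ct * (p[1] - yc)
    phi = math.atan2(y / b, x / a)
    best = min(
        math.hypot(x - a * math.cos(t), y - b * math.sin(t))
        for t in np.linspace(phi - 0.5, phi + 0.5, 41))
    return best


def grid_search_ellipse(pts):
    """Independent geometric least-squares oracle: coarse grid over the
    moment-ellipse neighborhood polished by Nelder-Mead on summed squared
    point-to-ellipse distances."""
    c0 = pts.mean(axis=0)
    cov = np.cov((pts - c0).T, bias=True)
    evals, evecs = np.linalg.eigh(cov)
    a0, b0 = np.sqrt(2 * evals[::-1])
    th0 = math.atan2(evecs[1, 1], evecs[0, 1]) % math.pi

    def cost(p):
        xc, yc, a, b, th = p
        if a <= 0 or b <= 0:
            return 1e12
        return sum(_point_to_ellipse_dist(q, xc, yc, a, b, th) ** 2
                   for q in pts)

    best, best_c = None, np.inf
    for fa in (0.95, 1.0, 1.05):
        for fb in (0.95, 1.0, 1.05):
            res = minimize(cost, [c0[0], c0[1], a0 * fa, b0 * fb, th0],
                           method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-10,
                                    "maxiter": 4000})
            if res.fun < best_c:
                best, best_c = res.x, res.fun
    return best


class TestFitEllipse:
    def test_exact_recovery(self):
        pts = ellipse_points(400, 250, theta=math.radians(30), n=100,
                             center=(1000, 2000))
        fit = geometry.fit_ellipse(pts)
        assert fit.axis_major == pytest.approx(800, abs=1e-6)
        assert fit.axis_minor == pytest.approx(500, abs=1e-6)
        assert fit.theta == pytest.approx(math.radians(30), abs=1e-6)
        assert not fit.from_moments

    def test_circle_gives_equal_axes(self):
        pts = ellipse_points(120, 120, n=60)
        fit = geometry.fit_ellipse(pts)
        assert fit.axis_major == pytest.approx(fit.axis_minor, rel=1e-9)
        assert fit.axis_major == pytest.approx(240, rel=1e-9)

    def test_point_order_irrelevant(self):
        pts = ellipse_points(300, 200, theta=0.7, n=50)
        rng = np.random.default_rng(3)
        shuffled = pts[rng.permutation(len(pts))]
        f1, f2 = geometry.fit_ellipse(pts), geometry.fit_ellipse(shuffled)
        assert f1.axis_major == pytest.approx(f2.axis_major, rel=1e-9)
        assert f1.theta == pytest.approx(f2.theta, abs=1e-9)

    def test_noisy_fit_matches_grid_search_oracle(self):
        pts = ellipse_points(400, 250, theta=0.5, n=120,
                             center=(500, 300), noise=2.0, seed=5)
        fit = geometry.fit_ellipse(pts)
        xc, yc, a, b, th = grid_search_ellipse(pts)
        assert fit.axis_major == pytest.approx(2 * a, rel=0.005)
        assert fit.axis_minor == pytest.approx(2 * b, rel=0.005)
        assert fit.center[0] == pytest.approx(xc, abs=0.005 * 400)
        assert fit.center[1] == pytest.approx(yc, abs=0.005 * 400)

    def test_too_few_points_error(self):
        with pytest.raises(ValueError, match=">= 6"):
            geometry.fit_ellipse(ellipse_points(10, 5, n=5))

    def test_collinear_error(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="collinear"):
            geometry.fit_ellipse(pts)


class TestValveMeasurement:
    def test_cyprideis_scale_convention(self):
        # semi-axes 454.5 x 261 um: full axes must land at the known
        # whole-valve scale (length ~909, height ~522, L/H ~1.74)
        pts = ellipse_points(454.5, 261.0, n=100)
        vm = geometry.valve_measurement(pts, "spec1", "L")
        assert vm.length == pytest.approx(909, rel=1e-6)
        assert vm.height == pytest.approx(522, rel=1e-6)
        assert vm.length / vm.height == pytest.approx(1.74, abs=0.01)
        assert vm.area == pytest.approx(math.pi * 454.5 * 261.0, rel=1e-3)

    def test_circle_log_shape_zero(self):
        vm = geometry.valve_measurement(ellipse_points(100, 100, n=80))
        assert vm.log_shape == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
    def test_scaling_law(self, k):
        pts = ellipse_points(300, 180, theta=0.3, n=90, noise=1.0, seed=2)
        vm1 = geometry.valve_measurement(pts)
        vm2 = geometry.valve_measurement(pts * k)
        assert vm2.area == pytest.approx(vm1.area * k * k, rel=1e-9)
        assert vm2.length == pytest.approx(vm1.length * k, rel=1e-9)
        assert vm2.log_shape == pytest.approx(vm1.log_shape, abs=1e-9)


class TestLengths:
    def test_collinear_polyline_equals_chord(self):
        pts = np.array([[0, 0], [1, 0], [5, 0]], float)
        assert geometry.polyline_length(pts) == pytest.approx(5.0)
        assert geometry.chord_length(pts) == pytest.approx(5.0)

    def test_semicircle_analytic_limit(self):
        t = np.linspace(0, np.pi, 1000)
        pts = np.column_stack([100 * np.cos(t), 100 * np.sin(t)])
        assert geometry.polyline_length(pts) == pytest.approx(
            math.pi * 100, rel=1e-5)

    def test_polyline_matches_pairwise_oracle(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 100, size=(30, 2))
        oracle = sum(math.dist(pts[i], pts[i + 1]) for i in range(29))
        assert geometry.polyline_length(pts) == pytest.approx(oracle, rel=1e-12)

    def test_u_shape_chord_zero(self):
        pts = np.array([[0, 0], [10, 0], [10, 10], [0, 10], [0, 0]], float)
        assert geometry.chord_length(pts) == 0.0
        assert geometry.polyline_length(pts) > 0

    def test_chord_is_3_4_5(self):
        pts = np.array([[0, 0], [1, 7], [3, 4]], float)
        assert geometry.chord_length(pts) == pytest.approx(5.0)

    @given(st.lists(st.tuples(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3)),
                    min_size=2, max_size=30))
    @settings(deadline=None, max_examples=100)
    def test_curve_never_shorter_than_chord(self, pts):
        pts = np.array(pts, float)
        assert (geometry.polyline_length(pts)
                >= geometry.chord_length(pts) - 1e-9)

    def test_too_few_points_errors(self):
        one = np.array([[0.0, 0.0]])
        with pytest.raises(ValueError):
            geometry.polyline_length(one)
        with pytest.raises(ValueError):
            geometry.chord_length(one)


class TestLandmarkDistance:
    def test_3_4_5_and_rigid_invariance(self):
        pts = np.array([[0, 0], [3, 4]], float)
        assert geometry.landmark_distance(pts, 0, 1) == pytest.approx(5.0)
        th = 1.1
        rot = np.array([[math.cos(th), -math.sin(th)],
                        [math.sin(th), math.cos(th)]])
        moved = pts @ rot.T + [77.0, -13.0]
        assert geometry.landmark_distance(moved, 0, 1) == pytest.approx(5.0)
        assert geometry.polyline_length(pts) == pytest.approx(5.0)

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            geometry.landmark_distance(np.array([[0, 0], [1, 1]], float), 0, 5)
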