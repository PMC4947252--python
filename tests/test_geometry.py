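"""Geometric primitives: closed-form checks, properties, cylinder fit."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from proxhum.errors import ConvergenceError, CylinderFitError, DegenerateGeometryError
from proxhum.geometry import (
    AxisLine,
    Plane,
    axial_coordinate,
    fit_cylinder_axis,
    line_plane_angle,
    plane_from_three_points,
    plane_plane_intersection,
    point_plane_signed_distance,
)
from .conftest import random_rotation

coord = st.floats(-100, 100, allow_nan=False, width=32)
point3 = st.tuples(coord, coord, coord).map(np.array)


def cylinder_points(rng, n, radius, z_span, noise=0.0):
    theta = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(0, z_span, n)
    r = radius + rng.normal(0, noise, n) if noise else radius
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


class TestPlaneFromThreePoints:
    @pytest.mark.parametrize("z", [0.0, 5.0])
    def test_coordinate_plane(self, z):
        plane = plane_from_three_points((0, 0, z), (1, 0, z), (0, 1, z))
        assert abs(abs(plane.normal[2]) - 1.0) < 1e-12
        assert abs(point_plane_signed_distance((10, -3, z), plane)) < 1e-9

    @given(point3, point3, point3)
    def test_contains_its_generators(self, p1, p2, p3):
        area2 = np.linalg.norm(np.cross(p2 - p1, p3 - p1))
        if area2 < 1e-6:
            return
        plane = plane_from_three_points(p1, p2, p3)
        for p in (p1, p2, p3):
            assert abs(point_plane_signed_distance(p, plane)) < 1e-9

    @pytest.mark.parametrize(
        "pts",
        [
            [(0, 0, 0), (1, 1, 1), (2, 2, 2)],  # collinear
            [(1, 2, 3), (1, 2, 3), (4, 5, 6)],  # coincident
        ],
    )
    def test_degenerate_points_rejected(self, pts):
        with pytest.raises(DegenerateGeometryError):
            plane_from_three_points(*pts)


class TestSignedDistanceAndAngle:
    def test_signed_distance_signs(self):
        z0 = Plane((0, 0, 0), (0, 0, 1))
        assert point_plane_signed_distance((0, 0, 7), z0) == pytest.approx(7)
        assert point_plane_signed_distance((5, -2, 0), z0) == 0
        assert point_plane_signed_distance((3, 4, -2), z0) == pytest.approx(-2)

    @pytest.mark.parametrize(
        "direction, expected",
        [
            ((0, 0, 1), 90.0),
            ((1, 0, 0), 0.0),
            # closed form: direction tilted 42.1 deg off +z -> 47.9 deg to z=0
            ((0, np.sin(np.radians(42.1)), np.cos(np.radians(42.1))), 47.9),
        ],
    )
    def test_line_plane_angle_closed_form(self, direction, expected):
        line = AxisLine((0, 0, 0), direction)
        z0 = Plane((0, 0, 0), (0, 0, 1))
        assert line_plane_angle(line, z0) == pytest.approx(expected, abs=1e-9)

    def test_angle_range_under_random_poses(self, rng):
        z0 = Plane((0, 0, 0), (0, 0, 1))
        for _ in range(50):
            line = AxisLine(rng.normal(size=3), rng.normal(size=3))
            a = line_plane_angle(line, z0)
            assert 0.0 <= a <= 90.0


class TestPlanePlaneIntersection:
    def test_coordinate_planes_give_x_axis(self):
        line = plane_plane_intersection(
            Plane((0, 0, 0), (0, 0, 1)), Plane((0, 0, 0), (0, 1, 0))
        )
        assert abs(abs(line.direction[0]) - 1.0) < 1e-12
        assert np.allclose(line.origin[[1, 2]], 0, atol=1e-12)

    def test_parallel_planes_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            plane_plane_intersection(
                Plane((0, 0, 0), (0, 0, 1)), Plane((0, 0, 1), (0, 0, 1))
            )

    def test_line_lies_on_both_planes(self, rng):
        for _ in range(10):
            a = Plane(rng.normal(size=3) * 10, rng.normal(size=3))
            b = Plane(rng.normal(size=3) * 10, rng.normal(size=3))
            if np.linalg.norm(np.cross(a.normal, b.normal)) < 1e-3:
                continue
            line = plane_plane_intersection(a, b)
            for t in np.linspace(-50, 50, 10):
                p = line.point_at(t)
                assert abs(point_plane_signed_distance(p, a)) < 1e-9
                assert abs(point_plane_signed_distance(p, b)) < 1e-9


class TestAxialCoordinate:
    def test_along_axis(self):
        axis = AxisLine((1, 2, 3), (0, 0, 1))
        assert axial_coordinate((1, 2, 3), axis) == 0
        assert axial_coordinate(np.array([1, 2, 3]) + 7.2 * axis.direction, axis) == pytest.approx(7.2)

    @given(st.floats(-50, 50), st.floats(-50, 50))
    def test_invariant_under_perpendicular_translation(self, a, b):
        axis = AxisLine((0, 0, 0), (0, 0, 1))
        p = np.array([1.0, -2.0, 13.5])
        q = p + np.array([a, b, 0.0])
        assert axial_coordinate(p, axis) == pytest.approx(axial_coordinate(q, axis))


class TestCylinderFit:
    def test_exact_recovery(self, rng):
        pts = cylinder_points(rng, 500, 12.5, 80.0)
        fit = fit_cylinder_axis(pts)
        angle = np.degrees(np.arccos(min(1.0, abs(fit.axis.direction @ [0, 0, 1]))))
        assert angle < 1e-6
        assert fit.radius == pytest.approx(12.5, abs=1e-6)
        assert fit.rms_residual < 1e-8

    def test_equivariance_under_rigid_motion(self, rng):
        pts = cylinder_points(rng, 500, 12.5, 80.0)
        R = random_rotation(rng)
        t = rng.uniform(-40, 40, 3)
        fit = fit_cylinder_axis(pts @ R.T + t)
        target = R @ np.array([0, 0, 1.0])
        angle = np.degrees(np.arccos(min(1.0, abs(fit.axis.direction @ target))))
        assert angle < 1e-6
        assert fit.radius == pytest.approx(12.5, abs=1e-6)

    def test_noisy_monte_carlo(self, rng):
        pts = cylinder_points(rng, 2000, 12.5, 80.0, noise=0.1)
        fit = fit_cylinder_axis(pts)
        angle = np.degrees(np.arccos(min(1.0, abs(fit.axis.direction @ [0, 0, 1]))))
        assert angle < 0.5
        assert fit.radius == pytest.approx(12.5, abs=0.05)

    def test_matches_grid_search_oracle(self, rng):
        """Axis orientation agrees with a brute-force search over directions."""
        axis_true = np.array([0.3, -0.2, 0.95])
        axis_true /= np.linalg.norm(axis_true)
        e1 = np.cross(axis_true, [1, 0, 0]); e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis_true, e1)
        theta = rng.uniform(0, 2 * np.pi, 200)
        z = rng.uniform(0, 50, 200)
        pts = 10.0 * (np.outer(np.cos(theta), e1) + np.outer(np.sin(theta), e2))
        pts += np.outer(z, axis_true)

        def cost(d):
            c = pts.mean(axis=0)
            q = pts - c
            radial = np.linalg.norm(q - np.outer(q @ d, d), axis=1)
            return np.var(radial)

        best, best_c = None, np.inf
        for az in np.radians(np.arange(0, 180, 2.0)):
            for el in np.radians(np.arange(-88, 90, 2.0)):
                d = np.array(
                    [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
                )
                c = cost(d)
                if c < best_c:
                    best, best_c = d, c
        fit = fit_cylinder_axis(pts, initial_axis=best)
        angle = np.degrees(np.arccos(min(1, abs(fit.axis.direction @ axis_true))))
        assert angle < 1e-6
        # the coarse grid itself lands within its 2-degree spacing
        grid_angle = np.degrees(np.arccos(min(1, abs(best @ axis_true))))
        assert grid_angle < 2.0

    @pytest.mark.parametrize(
        "pts",
        [
            np.zeros((3, 3)),  # too few
            np.column_stack([np.cos(np.linspace(0, 6, 50)),
                             np.sin(np.linspace(0, 6, 50)),
                             np.zeros(50)]),  # flat ring: no axial extent
        ],
    )
    def test_degenerate_clouds_rejected(self, pts):
        with pytest.raises((CylinderFitError, ConvergenceError)):
            fit_cylinder_axis(pts)


def test_primitive_rigid_motion_equivariance(rng):
    """Scalars from plane/axis constructions are pose-invariant."""
    p1, p2, p3 = rng.normal(size=(3, 3)) * 20
    q = rng.normal(size=3) * 20
    line = AxisLine(rng.normal(size=3), rng.normal(size=3))
    plane = plane_from_three_points(p1, p2, p3)
    d0 = point_plane_signed_distance(q, plane)
    a0 = line_plane_angle(line, plane)
    t0 = axial_coordinate(q, line)
    for _ in range(5):
        R = random_rotation(rng)
        t = rng.uniform(-30, 30, 3)
        plane_r = plane_from_three_points(R @ p1 + t, R @ p2 + t, R @ p3 + t)
        line_r = AxisLine(R @ line.origin + t, R @ line.direction)
        assert point_plane_signed_distance(R @ q + t, plane_r) == pytest.approx(d0, abs=1e-6)
        assert line_plane_angle(line_r, plane_r) == pytest.approx(a0, abs=1e-6)
        assert axial_coordinate(R @ q + t, line_r) == pytest.approx(t0, abs=1e-6)
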