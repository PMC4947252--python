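"""3-D measurement pipeline: closed forms, oracle identities, pose invariance."""

import numpy as np
import pytest
import trimesh

from proxhum.errors import (
    CylinderFitError,
    DegenerateGeometryError,
    MissingRegionError,
)
from proxhum.geometry import Plane, axial_coordinates, points_plane_signed_distance
from proxhum.mesh import TriangleMesh
from proxhum.morphometry import (
    axial_diameter,
    coronal_diameter,
    derive_shaft_axis,
    head_thickness,
    locate_point_F,
    locate_points_G_H,
    measure_proximal_humerus,
    neck_plane,
    neck_shaft_angle,
    tuberosity_height,
)
from proxhum.synthetic import HumerusParams, generate_humerus
from .conftest import random_rotation


def hemisphere_mesh(radius=25.0):
    """Upper half of an icosphere, labelled articular."""
    sphere = trimesh.creation.icosphere(subdivisions=4, radius=radius)
    labels = np.array(
        ["articular_surface" if z >= -1e-9 else "other" for z in sphere.vertices[:, 2]],
        dtype=object,
    )
    return TriangleMesh(sphere.vertices, sphere.faces, labels)


class TestPointFAndHeadThickness:
    def test_spherical_cap_closed_form(self, spherical_bone):
        """R=25 cut at d=7: the furthest articular point sits R-d=18 mm up."""
        mesh, lm, truth = spherical_bone
        plane1 = neck_plane(lm, mesh)
        assert head_thickness(mesh, plane1) == pytest.approx(18.0, abs=1e-9)

    def test_hemisphere_thickness_is_radius(self):
        mesh = hemisphere_mesh(25.0)
        plane1 = Plane((0, 0, 0), (0, 0, 1))
        # icosphere vertices include the pole exactly
        assert head_thickness(mesh, plane1) == pytest.approx(25.0, abs=1e-9)

    def test_equals_brute_force_argmax(self, coarse_bone):
        mesh, lm, _ = coarse_bone
        plane1 = neck_plane(lm, mesh)
        F = locate_point_F(mesh, plane1)
        idx = mesh.region_indices("articular_surface")
        d = points_plane_signed_distance(mesh.vertices[idx], plane1)
        assert np.allclose(F, mesh.vertices[idx[np.argmax(d)]])

    def test_orientation_error_when_head_fully_below_plane(self, coarse_bone):
        mesh, lm, _ = coarse_bone
        flipped = neck_plane(lm, mesh).flipped()
        above = Plane(flipped.point + 30.0 * flipped.normal, flipped.normal)
        from proxhum.errors import OrientationError

        with pytest.raises(OrientationError):
            locate_point_F(mesh, above)


class TestNeckShaftAngle:
    def test_reference_value(self):
        """alpha = 42.1 deg maps to NSA = 132.1 deg."""
        from proxhum.geometry import AxisLine

        g = np.radians(90 - 42.1)
        plane1 = Plane((0, 0, 0), (0, np.sin(g), np.cos(g)))
        axis = AxisLine((0, 0, 0), (0, 0, 1))
        alpha, nsa = neck_shaft_angle(plane1, axis)
        assert alpha == pytest.approx(42.1, abs=1e-9)
        assert nsa == pytest.approx(132.1, abs=1e-9)

    @pytest.mark.parametrize(
        "normal, expected_nsa",
        [((0, 1, 0), 90.0), ((0, 0, 1), 180.0)],  # plane holds axis / plane _|_ axis
    )
    def test_degenerate_orientations(self, normal, expected_nsa):
        from proxhum.geometry import AxisLine

        _, nsa = neck_shaft_angle(Plane((0, 0, 0), normal), AxisLine((0, 0, 0), (0, 0, 1)))
        assert nsa == pytest.approx(expected_nsa)


class TestSuperiorPoints:
    def test_argmax_oracle_identity(self, coarse_bone):
        mesh, _, _ = coarse_bone
        fit = derive_shaft_axis(mesh)
        G, H = locate_points_G_H(mesh, fit.axis)
        for region, point in (("articular_surface", G), ("greater_tuberosity", H)):
            idx = mesh.region_indices(region)
            t = axial_coordinates(mesh.vertices[idx], fit.axis)
            assert np.allclose(point, mesh.vertices[idx[np.argmax(t)]])

    def test_generator_ground_truth(self, coarse_bone):
        mesh, _, truth = coarse_bone
        fit = derive_shaft_axis(mesh)
        G, H = locate_points_G_H(mesh, fit.axis)
        assert G[2] == pytest.approx(truth.G[2], abs=0.02)
        assert np.allclose(H, truth.H, atol=1e-9)

    def test_missing_region_error(self, coarse_bone):
        mesh, _, _ = coarse_bone
        stripped = TriangleMesh(
            mesh.vertices,
            mesh.faces,
            np.where(
                mesh.region_labels == "greater_tuberosity", "other", mesh.region_labels
            ),
        )
        fit = derive_shaft_axis(stripped)
        with pytest.raises(MissingRegionError):
            locate_points_G_H(stripped, fit.axis)


class TestTuberosityHeight:
    def test_axial_difference(self):
        from proxhum.geometry import AxisLine

        axis = AxisLine((0, 0, 0), (0, 0, 1))
        assert tuberosity_height((0, 0, 100.0), (5, -3, 92.8), axis) == pytest.approx(7.2)
        assert tuberosity_height((1, 2, 3), (1, 2, 3), axis) == 0

    def test_rotation_invariance(self, rng):
        from proxhum.geometry import AxisLine

        G, H = np.array([3.0, -1.0, 50.0]), np.array([8.0, 2.0, 44.0])
        axis = AxisLine((0, 0, 0), (0, 0, 1))
        t0 = tuberosity_height(G, H, axis)
        R = random_rotation(rng)
        t = rng.uniform(-20, 20, 3)
        axis_r = AxisLine(R @ axis.origin + t, R @ axis.direction)
        assert tuberosity_height(R @ G + t, R @ H + t, axis_r) == pytest.approx(t0)


class TestDiameters:
    def test_coronal_diameter(self):
        assert coronal_diameter((0, 0, 0), (0, 44.2, 0)) == pytest.approx(44.2)
        with pytest.raises(DegenerateGeometryError):
            coronal_diameter((1, 2, 3), (1, 2, 3))

    def test_spherical_cap_chord(self, spherical_bone):
        """R=25, d=7 gives a rim chord of 2 sqrt(R^2-d^2) = 48 mm."""
        mesh, lm, _ = spherical_bone
        assert coronal_diameter(lm.C, lm.D) == pytest.approx(48.0, abs=1e-9)

    def test_spherical_symmetry_axial_equals_coronal(self, spherical_bone):
        mesh, lm, _ = spherical_bone
        plane1 = neck_plane(lm, mesh)
        aasd, I, J = axial_diameter(mesh, plane1, lm.C, lm.D)
        assert aasd == pytest.approx(48.0, rel=2e-3)

    def test_ellipsoidal_scaling(self):
        scale = 0.92
        params = HumerusParams(
            head_radius=25.0,
            neck_cut_distance=7.0,
            head_ap_scale=scale,
            mesh_edge_length=1.0,
        )
        mesh, lm, truth = generate_humerus(params)
        plane1 = neck_plane(lm, mesh)
        aasd, _, _ = axial_diameter(mesh, plane1, lm.C, lm.D)
        assert aasd == pytest.approx(scale * 48.0, rel=2e-3)
        assert truth.aasd_mm == pytest.approx(scale * 48.0)


class TestShaftAxis:
    def test_recovers_generator_axis(self, coarse_bone):
        mesh, _, truth = coarse_bone
        fit = derive_shaft_axis(mesh)
        angle = np.degrees(
            np.arccos(min(1, abs(fit.axis.direction @ truth.shaft_axis.direction)))
        )
        assert angle < 0.2
        assert fit.axis.direction[2] > 0  # canonicalised head-ward

    def test_tiny_shaft_region_rejected(self, coarse_bone):
        mesh, _, _ = coarse_bone
        labels = np.array(["other"] * mesh.n_vertices, dtype=object)
        shaft_idx = mesh.region_indices("shaft")[:3]
        labels[shaft_idx] = "shaft"
        labels[mesh.region_indices("articular_surface")] = "articular_surface"
        bad = TriangleMesh(mesh.vertices, mesh.faces, labels)
        with pytest.raises(CylinderFitError):
            derive_shaft_axis(bad)

    def test_axial_window_substitutes_for_labels(self, coarse_bone):
        mesh, _, truth = coarse_bone
        unlabelled = TriangleMesh(
            mesh.vertices,
            mesh.faces,
            np.where(mesh.region_labels == "shaft", "other", mesh.region_labels),
        )
        span = mesh.vertices[:, 2].max() - mesh.vertices[:, 2].min()
        fit = derive_shaft_axis(unlabelled, axial_window=(-0.45 * span, -0.1 * span))
        angle = np.degrees(
            np.arccos(min(1, abs(fit.axis.direction @ truth.shaft_axis.direction)))
        )
        assert angle < 1.0


class TestFullMeasurement:
    def test_recovery_against_ground_truth(self, coarse_bone):
        mesh, lm, truth = coarse_bone
        res = measure_proximal_humerus(mesh, lm)
        assert res.nsa_deg == pytest.approx(truth.nsa_deg, abs=0.5)
        assert res.hht_mm == pytest.approx(truth.hht_mm, rel=0.01)
        assert res.casd_mm == pytest.approx(truth.casd_mm, rel=0.01)
        assert res.aasd_mm == pytest.approx(truth.aasd_mm, rel=0.015)
        assert res.tsh_mm == pytest.approx(truth.tsh_mm, abs=0.2)
        assert res.nsa_deg == res.alpha_deg + 90.0

    def test_pose_invariance(self, coarse_bone, rng):
        mesh, lm, _ = coarse_bone
        base = measure_proximal_humerus(mesh, lm)
        R = random_rotation(rng)
        t = rng.uniform(-100, 100, 3)
        moved = measure_proximal_humerus(mesh.transformed(R, t), lm.transformed(R, t))
        for attr in ("nsa_deg", "hht_mm", "tsh_mm", "casd_mm", "aasd_mm"):
            a, b = getattr(base, attr), getattr(moved, attr)
            assert b == pytest.approx(a, rel=1e-3, abs=1e-3), attr

    def test_unlabelled_mesh_error_names_stage(self, coarse_bone):
        mesh, lm, _ = coarse_bone
        bare = TriangleMesh(
            mesh.vertices, mesh.faces, np.array(["other"] * mesh.n_vertices, dtype=object)
        )
        with pytest.raises(MissingRegionError, match="shaft_axis"):
            measure_proximal_humerus(bare, lm)

    def test_resolution_convergence(self):
        """Finer meshes do not measure worse (aASD and TSH carry the
        discretisation error; NSA/HHT/cASD are vertex-exact by design)."""
        errors = []
        for h in (2.0, 1.0, 0.5):
            mesh, lm, truth = generate_humerus(HumerusParams(mesh_edge_length=h))
            res = measure_proximal_humerus(mesh, lm)
            errors.append(
                abs(res.aasd_mm - truth.aasd_mm) + abs(res.tsh_mm - truth.tsh_mm)
            )
        assert errors[2] <= errors[0] + 1e-6
        assert errors[2] <= errors[1] + 1e-6
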