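import numpy as np
import pytest

import spinecongruence as sc
from spinecongruence.errors import DegenerateSampleError, InsufficientPointsError
from spinecongruence.shapes import Cylinder, Plane, Sphere


class TestDistances:
    @pytest.mark.parametrize(
        "model,point,expected",
        [
            (Plane(normal=(0, 0, 1), offset=0.0), (0, 0, 1), 1.0),
            (Sphere(center=(0, 0, 0), radius=1.0), (2, 0, 0), 1.0),
            (Cylinder(anchor=(0, 0, 0), direction=(0, 0, 1), radius=1.0), (2, 0, 5), 1.0),
        ],
    )
    def test_point_to_surface(self, model, point, expected):
        assert sc.distance_to_shape(model, np.array([point])) == pytest.approx(expected)

    def test_distances_are_nonnegative(self, rng):
        pts = rng.normal(0, 10, (200, 3))
        for model in (
            Plane(normal=(1, 2, 2), offset=3.0),
            Sphere(center=(1, -2, 0), radius=4.0),
            Cylinder(anchor=(0, 1, 0), direction=(1, 1, 0), radius=2.0),
        ):
            assert np.all(sc.distance_to_shape(model, pts) >= 0)


class TestCanonicalization:
    def test_plane_normal_sign_fixed(self):
        a = Plane(normal=(0, 0, 1), offset=-2.0)
        b = Plane(normal=(0, 0, -1), offset=2.0)
        assert np.allclose(a.normal, b.normal)
        assert a.offset == b.offset

    def test_cylinder_anchor_nearest_origin(self):
        c = Cylinder(anchor=(5, 5, 100), direction=(0, 0, -1), radius=2.0)
        assert np.allclose(c.direction, [0, 0, 1])  # sign-canonical
        assert c.anchor @ c.direction == pytest.approx(0.0)  # perpendicular foot

    def test_positive_radius_required(self):
        with pytest.raises(ValueError):
            Sphere(center=(0, 0, 0), radius=0.0)
        with pytest.raises(ValueError):
            Cylinder(anchor=(0, 0, 0), direction=(0, 0, 1), radius=-1.0)


class TestMinimalPlane:
    def test_through_origin_triangle(self):
        p = sc.fit_plane_minimal((0, 0, 0), (1, 0, 0), (0, 1, 0))
        assert np.allclose(p.normal, [0, 0, 1])
        assert p.offset == pytest.approx(0.0)

    def test_offset_plane(self):
        p = sc.fit_plane_minimal((0, 0, 1), (1, 0, 1), (0, 1, 1))
        assert np.allclose(p.normal, [0, 0, 1])
        assert p.offset == pytest.approx(-1.0)

    def test_contains_sample_points(self, rng):
        pts = rng.normal(0, 5, (3, 3))
        p = sc.fit_plane_minimal(*pts)
        assert np.all(sc.distance_to_shape(p, pts) < 1e-9)

    def test_collinear_rejected(self):
        with pytest.raises(DegenerateSampleError):
            sc.fit_plane_minimal((0, 0, 0), (1, 1, 1), (2, 2, 2))


class TestMinimalSphere:
    def test_unit_circumsphere(self):
        s = sc.fit_sphere_minimal((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, 0, 1))
        assert np.allclose(s.center, [0, 0, 0], atol=1e-12)
        assert s.radius == pytest.approx(1.0)

    def test_coplanar_rejected(self):
        with pytest.raises(DegenerateSampleError):
            sc.fit_sphere_minimal((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0))

    def test_recovers_random_sphere(self, rng):
        center, radius = np.array([3.0, -2.0, 7.0]), 5.0
        for _ in range(20):
            u = rng.normal(size=(4, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            s = sc.fit_sphere_minimal(*(center + radius * u))
            assert np.allclose(s.center, center, atol=1e-6)
            assert s.radius == pytest.approx(radius, abs=1e-6)


class TestMinimalCylinder:
    def test_unit_cylinder_about_z(self):
        c = sc.fit_cylinder_minimal((1, 0, 0), (1, 0, 0), (0, 1, 4), (0, 1, 0))
        assert np.allclose(c.direction, [0, 0, 1])
        assert np.allclose(c.anchor, [0, 0, 0], atol=1e-12)
        assert c.radius == pytest.approx(1.0)

    def test_radius_two(self):
        c = sc.fit_cylinder_minimal((2, 0, 0), (1, 0, 0), (0, 2, 9), (0, 1, 0))
        assert np.allclose(np.abs(c.direction), [0, 0, 1])
        assert c.radius == pytest.approx(2.0)

    def test_parallel_normals_rejected(self):
        with pytest.raises(DegenerateSampleError):
            sc.fit_cylinder_minimal((1, 0, 0), (0, 0, 1), (0, 1, 0), (0, 0, 1))

    def test_sign_invariant_in_normals(self):
        a = sc.fit_cylinder_minimal((1, 0, 0), (1, 0, 0), (0, 1, 4), (0, 1, 0))
        b = sc.fit_cylinder_minimal((1, 0, 0), (-1, 0, 0), (0, 1, 4), (0, -1, 0))
        assert np.allclose(a.anchor, b.anchor)
        assert np.allclose(a.direction, b.direction)
        assert a.radius == pytest.approx(b.radius)


class TestRefine:
    def test_perturbed_plane_snaps_back(self, rng):
        pts = np.column_stack([rng.uniform(-5, 5, (50, 2)), np.zeros(50)])
        rough = Plane(normal=(0.05, -0.02, 1.0), offset=0.3)
        refined = sc.refine_fit(rough, pts)
        assert np.all(sc.distance_to_shape(refined, pts) < 1e-9)

    def test_sphere_radius_converges(self, rng):
        u = rng.normal(size=(200, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        refined = sc.refine_fit(Sphere(center=(0.05, 0, 0), radius=1.1), u)
        assert refined.radius == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(refined.center, [0, 0, 0], atol=1e-6)

    def test_cylinder_converges(self, rng):
        theta = rng.uniform(0, 2 * np.pi, 300)
        z = rng.uniform(-5, 5, 300)
        pts = np.column_stack([10 * np.cos(theta), 10 * np.sin(theta), z])
        rough = Cylinder(anchor=(0.2, -0.1, 0), direction=(0.02, 0.01, 1.0), radius=9.7)
        refined = sc.refine_fit(rough, pts)
        assert refined.radius == pytest.approx(10.0, abs=1e-6)
        assert np.allclose(np.abs(refined.direction), [0, 0, 1], atol=1e-6)

    def test_never_worsens_rmse(self, rng):
        pts = rng.normal(0, 3, (100, 3))  # pure noise, no structure
        model = Sphere(center=(0, 0, 0), radius=3.0)
        before = float(np.sqrt(np.mean(sc.distance_to_shape(model, pts) ** 2)))
        refined = sc.refine_fit(model, pts)
        after = float(np.sqrt(np.mean(sc.distance_to_shape(refined, pts) ** 2)))
        assert after <= before + 1e-9

    def test_too_few_inliers(self):
        with pytest.raises(InsufficientPointsError):
            sc.refine_fit(Sphere(center=(0, 0, 0), radius=1.0), np.zeros((2, 3)))
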