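import numpy as np
import pytest

import spinecongruence as sc
from spinecongruence.errors import SpineCongruenceError
from spinecongruence.shapes import Cylinder, Plane, Sphere
from spinecongruence.synthetic import REGION_PRESETS, region_of_level


class TestPrimitivePatch:
    def test_noise_free_plane_on_surface(self):
        model = Plane(normal=(0, 0, 1), offset=-2.0)
        cloud = sc.generate_primitive_patch(model, n=100, seed=1)
        assert len(cloud) == 100
        assert np.all(sc.distance_to_shape(model, cloud.points) < 1e-9)
        assert set(cloud.labels) == {"surface"}

    def test_outlier_count_by_construction(self):
        model = Sphere(center=(0, 0, 0), radius=10.0)
        cloud = sc.generate_primitive_patch(model, n=1000, outlier_fraction=0.3, seed=2)
        assert int(np.sum(cloud.labels == "surface")) == 700
        assert int(np.sum(cloud.labels == "outlier")) == 300
        d = sc.distance_to_shape(model, cloud.points[cloud.labels == "outlier"])
        assert np.all(d > 2.0)

    def test_full_outlier_fraction_rejected(self):
        model = Plane(normal=(0, 0, 1), offset=0.0)
        with pytest.raises(SpineCongruenceError):
            sc.generate_primitive_patch(model, n=100, outlier_fraction=1.0)

    def test_cylinder_patch_on_surface(self):
        model = Cylinder(anchor=(0, 0, 0), direction=(0, 1, 0), radius=14.0)
        cloud = sc.generate_primitive_patch(model, n=300, seed=3)
        assert np.all(sc.distance_to_shape(model, cloud.points) < 1e-9)

    def test_deterministic_per_seed(self):
        model = Sphere(center=(1, 2, 3), radius=8.0)
        a = sc.generate_primitive_patch(model, n=200, noise_sd=0.1, outlier_fraction=0.2, seed=9)
        b = sc.generate_primitive_patch(model, n=200, noise_sd=0.1, outlier_fraction=0.2, seed=9)
        assert np.array_equal(a.points, b.points)
        assert np.array_equal(a.labels, b.labels)


class TestVertebra:
    def test_label_partition_exhaustive(self, default_vertebra):
        known = {
            "left_hemilamina", "right_hemilamina", "sp_base", "sp_tip",
            "facet", "outlier",
        }
        assert set(default_vertebra.labels) <= known
        assert len(default_vertebra) == 2000

    def test_bare_arch_is_exact_cylinder(self, noisefree_vertebra):
        true = Cylinder(anchor=(0, 0, 0), direction=(0, 1, 0), radius=14.0)
        d = sc.distance_to_shape(true, noisefree_vertebra.points)
        assert np.all(d < 1e-9)
        fit = sc.ransac_fit(
            noisefree_vertebra, sc.RansacConfig("cylinder", epsilon=0.5, seed=1)
        )
        assert fit.itpr == 1.0

    def test_lateral_spread_beyond_sp_band(self, default_vertebra):
        x = default_vertebra.points[:, 0]
        assert np.median(np.abs(x)) > 4.0  # most points lie outside the SP band

    def test_sp_height_monotonically_disrupts_group_b_cylinder(self):
        itprs = []
        for h in (0.0, 4.0, 8.0, 12.0):
            v = sc.generate_vertebra(
                sc.VertebraParams(
                    sp_height=h, noise_sd=0.0, outlier_fraction=0.0,
                    points_per_level=1500, seed=21,
                )
            )
            sub = sc.reconstruct_group(v, "B", "right")
            fit = sc.ransac_fit(sub, sc.RansacConfig("cylinder", seed=5))
            itprs.append(fit.itpr)
        for prev, nxt in zip(itprs, itprs[1:]):
            assert nxt <= prev + 0.02

    def test_reflection_preserves_itpr(self):
        v = sc.generate_vertebra(sc.VertebraParams(points_per_level=1500, seed=8))
        mirrored = sc.PointCloud(v.points * np.array([-1.0, 1.0, 1.0]), labels=v.labels)
        for kind in ("plane", "sphere", "cylinder"):
            cfg = sc.RansacConfig(kind, seed=4)
            assert sc.ransac_fit(v, cfg).itpr == pytest.approx(
                sc.ransac_fit(mirrored, cfg).itpr, abs=1e-12
            )

    def test_reproducible_per_seed(self):
        p = sc.VertebraParams(points_per_level=800, seed=17)
        a, b = sc.generate_vertebra(p), sc.generate_vertebra(p)
        assert np.array_equal(a.points, b.points)
        assert np.array_equal(a.labels, b.labels)

    def test_invalid_params(self):
        with pytest.raises(SpineCongruenceError):
            sc.VertebraParams(outlier_fraction=1.0)
        with pytest.raises(SpineCongruenceError):
            sc.VertebraParams(points_per_level=100)
        with pytest.raises(SpineCongruenceError):
            sc.VertebraParams(arch_radius=-1.0)


class TestCohort:
    def test_level_region_mapping(self):
        assert region_of_level("C1") == "c1"
        assert region_of_level("C5") == "subaxial_cervical"
        assert region_of_level("T7") == "thoracic"
        assert region_of_level("L4") == "lumbar"
        assert region_of_level("S1") == "sacral"
        with pytest.raises(SpineCongruenceError):
            region_of_level("T13")

    def test_cohort_size(self):
        spec = sc.CohortSpec(
            n_specimens=2,
            levels=("C1", "T5", "L3"),
            base_params=sc.VertebraParams(points_per_level=600),
            seed=1,
        )
        cohort = sc.generate_cohort(spec)
        assert len(cohort) == 6
        assert ("S2", "L3") in cohort

    def test_zero_jitter_gives_identical_specimens(self):
        spec = sc.CohortSpec(
            n_specimens=3,
            levels=("C4",),
            jitter_sd=0.0,
            base_params=sc.VertebraParams(points_per_level=600),
            seed=2,
        )
        cohort = sc.generate_cohort(spec)
        ref = cohort[("S1", "C4")]
        for s in ("S2", "S3"):
            assert np.array_equal(cohort[(s, "C4")].points, ref.points)

    def test_cervical_more_cylindrical_than_lumbar(self):
        """Noise-free regional presets: the smoother, wider cervical arch
        shows higher unilateral cylindrical congruence than the lumbar."""
        itpr = {}
        for region, level in (("subaxial_cervical", "C5"), ("lumbar", "L3")):
            params = sc.VertebraParams(
                noise_sd=0.0, outlier_fraction=0.0, points_per_level=1500,
                seed=31, **REGION_PRESETS[region],
            )
            sub = sc.reconstruct_group(sc.generate_vertebra(params), "C", "left")
            itpr[region] = sc.ransac_fit(sub, sc.RansacConfig("cylinder", seed=6)).itpr
        assert itpr["subaxial_cervical"] > itpr["lumbar"]

    def test_cohort_reproducible(self):
        spec = sc.CohortSpec(
            n_specimens=2, levels=("T1",), seed=5,
            base_params=sc.VertebraParams(points_per_level=600),
        )
        a, b = sc.generate_cohort(spec), sc.generate_cohort(spec)
        for key in a:
            assert np.array_equal(a[key].points, b[key].points)
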