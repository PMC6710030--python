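import numpy as np
import pytest

import spinecongruence as sc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def plane_grid():
    """100-point grid on the plane z = 0."""
    xs, ys = np.meshgrid(np.linspace(-5, 5, 10), np.linspace(-5, 5, 10))
    pts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(100)])
    return sc.PointCloud(pts)


@pytest.fixture
def noisefree_vertebra():
    """Arch-only vertebra: no ridge, no facets, no noise, no outliers."""
    return sc.generate_vertebra(
        sc.VertebraParams(
            sp_height=0.0,
            facet_count_per_side=0,
            noise_sd=0.0,
            outlier_fraction=0.0,
            points_per_level=800,
            seed=7,
        )
    )


@pytest.fixture
def default_vertebra():
    return sc.generate_vertebra(sc.VertebraParams(points_per_level=2000, seed=3))
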