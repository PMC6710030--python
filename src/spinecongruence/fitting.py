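"""Seeded RANSAC primitive fitting and k-NN normal estimation.

The fit quality metric is the inliers-to-points ratio (ITPR): the fraction
of the cloud within the maximum inlier error ``epsilon`` of the fitted
surface.  High ITPR on a symmetric primitive means high geometric
congruence and therefore elevated risk of ambiguous surface registration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .errors import (
    DegenerateSampleError,
    InsufficientPointsError,
    NoValidHypothesisError,
)
from .shapes import (
    MINIMAL_SAMPLE_SIZE,
    ShapeModel,
    distance_to_shape,
    fit_cylinder_minimal,
    fit_plane_minimal,
    fit_sphere_minimal,
    refine_fit,
)

__all__ = ["RansacConfig", "FitResult", "estimate_normals", "ransac_fit"]


@dataclass(frozen=True)
class RansacConfig:
    """Configuration of one RANSAC fit.

    ``epsilon`` is the maximum inlier error in mm (point-to-surface
    Euclidean distance); ``iterations`` is the exact number of hypothesis
    draws (degenerate samples consume an iteration); ``refine`` polishes
    the winning model by least squares and re-derives the inlier mask once
    against the refined model; ``normal_k`` is the k-NN neighbourhood used
    when cylinder fitting must estimate normals on demand.
    """

    shape_kind: str
    epsilon: float = 0.5
    iterations: int = 100
    seed: int = 0
    refine: bool = True
    normal_k: int = 20

    def __post_init__(self):
        if self.shape_kind not in MINIMAL_SAMPLE_SIZE:
            raise ValueError(f"unknown shape kind {self.shape_kind!r}")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.normal_k < 3:
            raise ValueError("normal_k must be >= 3")


@dataclass(frozen=True)
class FitResult:
    """Winning RANSAC model with its inlier mask and quality metrics.

    ``itpr`` = inliers / total points; ``rmse`` is the root-mean-square
    inlier distance to the surface (mm, <= epsilon by construction);
    ``rmse_all`` is the same over every point, reported alongside because
    published descriptions of cloud-to-shape RMSE are ambiguous about
    inlier restriction.
    """

    model: ShapeModel
    inlier_mask: np.ndarray
    itpr: float
    rmse: float
    rmse_all: float
    iterations_run: int
    seed: int

    def to_dict(self) -> dict:
        m = self.model
        if m.kind == "plane":
            params = {"normal": list(m.normal), "offset": m.offset}
        elif m.kind == "sphere":
            params = {"center": list(m.center), "radius": m.radius}
        else:
            params = {
                "anchor": list(m.anchor),
                "direction": list(m.direction),
                "radius": m.radius,
            }
        return {
            "shape": m.kind,
            "model": params,
            "itpr": self.itpr,
            "rmse": self.rmse,
            "rmse_all": self.rmse_all,
            "n_points": int(len(self.inlier_mask)),
            "n_inliers": int(self.inlier_mask.sum()),
            "iterations_run": self.iterations_run,
            "seed": self.seed,
        }


def estimate_normals(cloud: PointCloud, k: int = 20) -> PointCloud:
    """Per-point unit normals from local PCA over the k nearest neighbours.

    The normal is the least-variance principal direction of each point's
    k-neighbourhood (the point itself included).  Signs are fixed to the
    +z hemisphere, breaking ties toward +y then +x — an arbitrary but
    deterministic convention; the two-point cylinder estimator is
    sign-invariant.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    pts = cloud.points
    if len(pts) < k:
        raise InsufficientPointsError(
            f"normal estimation needs >= k={k} points, got {len(pts)}"
        )
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k)
    neigh = pts[idx]  # (N, k, 3)
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / k
    _, vecs = np.linalg.eigh(cov)  # ascending eigenvalues
    normals = vecs[:, :, 0]
    # orient toward the +z hemisphere (ties: +y, then +x)
    flip = (
        (normals[:, 2] < 0)
        | ((normals[:, 2] == 0) & (normals[:, 1] < 0))
        | ((normals[:, 2] == 0) & (normals[:, 1] == 0) & (normals[:, 0] < 0))
    )
    normals[flip] *= -1.0
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return PointCloud(points=pts, normals=normals, labels=cloud.labels)


def _hypothesis(kind: str, pts: np.ndarray, normals, sample: np.ndarray) -> ShapeModel:
    if kind == "plane":
        return fit_plane_minimal(*pts[sample])
    if kind == "sphere":
        return fit_sphere_minimal(*pts[sample])
    i, j = sample
    return fit_cylinder_minimal(pts[i], normals[i], pts[j], normals[j])


def ransac_fit(cloud: PointCloud, config: RansacConfig) -> FitResult:
    """Random-sample-consensus fit of one primitive kind to a cloud.

    Runs exactly ``config.iterations`` minimal-sample draws (without
    replacement within a draw; degenerate samples count as spent
    iterations), keeps the hypothesis with the most inliers at tolerance
    ``epsilon`` — ties broken by lower inlier RMSE, then earlier iteration
    — and optionally refines the winner on its inlier set, re-deriving the
    mask once against the refined model.  Deterministic given the cloud
    point order and ``config.seed``.
    """
    kind = config.shape_kind
    m = MINIMAL_SAMPLE_SIZE[kind]
    pts = cloud.points
    n = len(pts)
    if n < m:
        raise InsufficientPointsError(
            f"{kind} fitting needs >= {m} points, got {n}"
        )
    normals = cloud.normals
    if kind == "cylinder" and normals is None:
        normals = estimate_normals(cloud, k=config.normal_k).normals

    rng = np.random.default_rng(config.seed)
    best = None  # (count, rmse, iteration, model, mask, dists)
    for it in range(config.iterations):
        sample = rng.choice(n, size=m, replace=False)
        try:
            model = _hypothesis(kind, pts, normals, sample)
        except DegenerateSampleError:
            continue
        d = distance_to_shape(model, pts)
        mask = d <= config.epsilon
        count = int(mask.sum())
        rmse = float(np.sqrt(np.mean(d[mask] ** 2))) if count else np.inf
        key = (-count, rmse, it)
        if best is None or key < best[0]:
            best = (key, model, mask, d)

    if best is None:
        raise NoValidHypothesisError(
            f"all {config.iterations} iterations drew degenerate samples"
        )
    _, model, mask, d = best

    if config.refine and int(mask.sum()) >= {"plane": 3, "sphere": 4, "cylinder": 5}[kind]:
        refined = refine_fit(model, pts[mask])
        d = distance_to_shape(refined, pts)
        mask = d <= config.epsilon
        model = refined

    count = int(mask.sum())
    rmse = float(np.sqrt(np.mean(d[mask] ** 2))) if count else 0.0
    return FitResult(
        model=model,
        inlier_mask=mask,
        itpr=count / n,
        rmse=rmse,
        rmse_all=float(np.sqrt(np.mean(d**2))),
        iterations_run=config.iterations,
        seed=config.seed,
    )
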