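"""Parametric symmetric primitives: plane, sphere, cylinder.

These are the three congruent geometries that make iterative closest-point
registration ambiguous — a surface well fitted by any of them admits a
family of rigid motions that leave the fit unchanged.  Each model knows its
point-to-surface distance, a minimal-sample constructor for RANSAC
hypothesis generation, and a least-squares refinement.

Model representations are canonicalized so equality is well defined:
the lexicographically larger of {n, -n} (plane normal) and {v, -v}
(cylinder axis) is stored, and the cylinder anchor is the axis point
closest to the origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateSampleError, InsufficientPointsError

__all__ = [
    "Plane",
    "Sphere",
    "Cylinder",
    "ShapeModel",
    "SHAPE_KINDS",
    "MINIMAL_SAMPLE_SIZE",
    "distance_to_shape",
    "fit_plane_minimal",
    "fit_sphere_minimal",
    "fit_cylinder_minimal",
    "refine_fit",
]

SHAPE_KINDS = ("plane", "sphere", "cylinder")

#: Points needed for a minimal hypothesis (cylinder uses 2 *oriented* points).
MINIMAL_SAMPLE_SIZE = {"plane": 3, "sphere": 4, "cylinder": 2}


def _canonical_direction(v: np.ndarray) -> np.ndarray:
    """Unit vector, sign-fixed to the lexicographically larger of {v, -v}."""
    v = np.asarray(v, dtype=float)
    v = v / np.linalg.norm(v)
    if tuple(v) < tuple(-v):
        v = -v
    return v


@dataclass(frozen=True)
class Plane:
    """Surface {p : n . p + d = 0} with unit normal ``n`` and offset ``d`` (mm)."""

    normal: np.ndarray
    offset: float
    kind: str = "plane"

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        n = n / np.linalg.norm(n)
        d = float(self.offset)
        if tuple(n) < tuple(-n):  # flipping n flips d to keep the same surface
            n, d = -n, -d
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "offset", d)

    def distances(self, points: np.ndarray) -> np.ndarray:
        return np.abs(np.asarray(points, dtype=float) @ self.normal + self.offset)


@dataclass(frozen=True)
class Sphere:
    """Sphere with center ``c`` (mm) and radius ``r`` (mm > 0)."""

    center: np.ndarray
    radius: float
    kind: str = "sphere"

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError("sphere radius must be positive")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "radius", float(self.radius))

    def distances(self, points: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(np.asarray(points, dtype=float) - self.center, axis=1)
        return np.abs(d - self.radius)


@dataclass(frozen=True)
class Cylinder:
    """Infinite cylinder: axis anchor ``a``, unit direction ``v``, radius ``r``.

    Canonical form stores the anchor as the axis point nearest the origin
    and the sign-fixed direction.
    """

    anchor: np.ndarray
    direction: np.ndarray
    radius: float
    kind: str = "cylinder"

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError("cylinder radius must be positive")
        v = _canonical_direction(self.direction)
        a = np.asarray(self.anchor, dtype=float)
        a = a - (a @ v) * v  # closest point on axis to origin
        object.__setattr__(self, "direction", v)
        object.__setattr__(self, "anchor", a)
        object.__setattr__(self, "radius", float(self.radius))

    def distances(self, points: np.ndarray) -> np.ndarray:
        rel = np.asarray(points, dtype=float) - self.anchor
        axial = rel @ self.direction
        radial = rel - axial[:, None] * self.direction
        return np.abs(np.linalg.norm(radial, axis=1) - self.radius)


ShapeModel = Plane | Sphere | Cylinder


def distance_to_shape(model: ShapeModel, points: np.ndarray) -> np.ndarray:
    """Unsigned Euclidean point-to-surface distances in mm."""
    return model.distances(points)


# ---------------------------------------------------------------------------
# minimal-sample estimators (RANSAC hypothesis generators)
# ---------------------------------------------------------------------------

def fit_plane_minimal(p1, p2, p3) -> Plane:
    """Plane through three non-collinear points."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    cross = np.cross(p2 - p1, p3 - p1)
    scale = max(
        np.linalg.norm(p2 - p1), np.linalg.norm(p3 - p1), np.linalg.norm(p3 - p2)
    )
    if np.linalg.norm(cross) < 1e-9 * max(scale, 1e-12) * scale:
        raise DegenerateSampleError("collinear points do not define a plane")
    n = cross / np.linalg.norm(cross)
    return Plane(normal=n, offset=-float(n @ p1))


def fit_sphere_minimal(p1, p2, p3, p4) -> Sphere:
    """Unique sphere through four non-coplanar points.

    Equating squared distances to the unknown center gives the linear
    system 2 (p_i - p_4) . c = |p_i|^2 - |p_4|^2, i = 1..3.
    """
    pts = np.array([p1, p2, p3, p4], dtype=float)
    a = 2.0 * (pts[:3] - pts[3])
    b = np.sum(pts[:3] ** 2, axis=1) - np.sum(pts[3] ** 2)
    det = np.linalg.det(a)
    scale = np.max(np.abs(a)) or 1.0
    if abs(det) < 1e-9 * scale**3:
        raise DegenerateSampleError("coplanar points do not define a sphere")
    center = np.linalg.solve(a, b)
    radius = float(np.linalg.norm(pts[3] - center))
    if radius <= 0:
        raise DegenerateSampleError("degenerate sphere sample")
    return Sphere(center=center, radius=radius)


def fit_cylinder_minimal(p1, n1, p2, n2) -> Cylinder:
    """Cylinder from two oriented surface points.

    The axis direction is n1 x n2 (surface normals of a cylinder are
    perpendicular to its axis); the axis position is the least-squares
    intersection of the two normal lines projected onto the plane
    perpendicular to the axis; the radius is the mean distance of the two
    projected points to the axis.
    """
    p1, n1, p2, n2 = (np.asarray(x, dtype=float) for x in (p1, n1, p2, n2))
    v = np.cross(n1, n2)
    if np.linalg.norm(v) <= 1e-6:
        raise DegenerateSampleError("parallel normals do not define a cylinder axis")
    v = v / np.linalg.norm(v)

    # project everything onto the plane perpendicular to v
    proj = np.eye(3) - np.outer(v, v)
    q1, q2 = proj @ p1, proj @ p2
    d1 = proj @ n1
    d2 = proj @ n2
    d1 /= np.linalg.norm(d1)
    d2 /= np.linalg.norm(d2)

    # least-squares point closest to both lines {q_i + t d_i}; the v v^T
    # term pins the (free) axial coordinate so the 3x3 system is invertible
    m = (np.eye(3) - np.outer(d1, d1)) + (np.eye(3) - np.outer(d2, d2)) + np.outer(v, v)
    rhs = (np.eye(3) - np.outer(d1, d1)) @ q1 + (np.eye(3) - np.outer(d2, d2)) @ q2
    axis_point = np.linalg.solve(m, rhs)

    r = 0.5 * (np.linalg.norm(q1 - axis_point) + np.linalg.norm(q2 - axis_point))
    if r <= 0:
        raise DegenerateSampleError("zero-radius cylinder sample")
    return Cylinder(anchor=axis_point, direction=v, radius=r)


# ---------------------------------------------------------------------------
# least-squares refinement
# ---------------------------------------------------------------------------

def _fit_plane_lsq(points: np.ndarray) -> Plane:
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid, full_matrices=False)
    n = vt[-1]  # least-variance principal direction
    return Plane(normal=n, offset=-float(n @ centroid))


def _rmse(model: ShapeModel, points: np.ndarray) -> float:
    return float(np.sqrt(np.mean(model.distances(points) ** 2)))


def refine_fit(model: ShapeModel, points: np.ndarray, max_nfev: int = 200) -> ShapeModel:
    """Least-squares polish of a model on its inlier points.

    Plane: closed form via principal directions.  Sphere and cylinder:
    trust-region least squares on signed surface residuals, initialized at
    the input model.  If refinement fails to improve the RMSE (within
    1e-9), the input model is returned unchanged with a warning.
    """
    points = np.asarray(points, dtype=float)
    # cylinder needs 5 unoriented points (5 dof) — its 2-point minimal
    # sample only works because it also uses normals
    need = {"plane": 3, "sphere": 4, "cylinder": 5}[model.kind]
    if len(points) < need:
        raise InsufficientPointsError(
            f"need >= {need} inliers to refine a {model.kind}, got {len(points)}"
        )

    if model.kind == "plane":
        return _fit_plane_lsq(points)

    if model.kind == "sphere":
        def residual(x):
            c, r = x[:3], x[3]
            return np.linalg.norm(points - c, axis=1) - r

        x0 = np.concatenate([model.center, [model.radius]])
        sol = least_squares(residual, x0, max_nfev=max_nfev)
        refined = None
        if sol.x[3] > 0:
            refined = Sphere(center=sol.x[:3], radius=float(sol.x[3]))
    else:  # cylinder
        def residual(x):
            a, v_raw, r = x[:3], x[3:6], x[6]
            v = v_raw / np.linalg.norm(v_raw)
            rel = points - a
            radial = rel - (rel @ v)[:, None] * v
            return np.linalg.norm(radial, axis=1) - r

        x0 = np.concatenate([model.anchor, model.direction, [model.radius]])
        sol = least_squares(residual, x0, max_nfev=max_nfev)
        refined = None
        if sol.x[6] > 0 and np.linalg.norm(sol.x[3:6]) > 1e-12:
            refined = Cylinder(
                anchor=sol.x[:3], direction=sol.x[3:6], radius=float(sol.x[6])
            )

    if refined is not None and _rmse(refined, points) <= _rmse(model, points) + 1e-9:
        return refined
    warnings.warn(
        f"{model.kind} refinement did not improve the fit; keeping input model",
        RuntimeWarning,
        stacklevel=2,
    )
    return model
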