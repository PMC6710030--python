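"""Independent brute-force oracles for the RANSAC suite.

Exhaustive enumeration of every minimal sample, written from the geometry
directly (no code shared with the package's estimators), so the RANSAC
winner can be compared against the global optimum of its hypothesis
space.
"""

from itertools import combinations

import numpy as np


def best_plane_inlier_count(pts: np.ndarray, eps: float) -> int:
    """Max inlier count over every 3-point plane hypothesis."""
    n = len(pts)
    combos = np.array(list(combinations(range(n), 3)))
    p1, p2, p3 = pts[combos[:, 0]], pts[combos[:, 1]], pts[combos[:, 2]]
    normals = np.cross(p2 - p1, p3 - p1)
    norms = np.linalg.norm(normals, axis=1)
    ok = norms > 1e-12
    normals = normals[ok] / norms[ok, None]
    rel = pts[None, :, :] - p1[ok][:, None, :]
    d = np.abs(np.einsum("mnk,mk->mn", rel, normals))
    return int((d <= eps).sum(axis=1).max())


def best_sphere_inlier_count(pts: np.ndarray, eps: float) -> int:
    """Max inlier count over every 4-point circumsphere hypothesis."""
    n = len(pts)
    combos = np.array(list(combinations(range(n), 4)))
    q = pts[combos]  # (M, 4, 3)
    a = 2.0 * (q[:, :3] - q[:, 3:4])  # (M, 3, 3)
    b = np.sum(q[:, :3] ** 2, axis=2) - np.sum(q[:, 3] ** 2, axis=1)[:, None]
    det = np.linalg.det(a)
    ok = np.abs(det) > 1e-9
    centers = np.linalg.solve(a[ok], b[ok][..., None])[..., 0]
    radii = np.linalg.norm(q[ok][:, 3] - centers, axis=1)
    best = 0
    chunk = 20000  # bound peak memory of the (M, n) distance matrix
    for i in range(0, len(centers), chunk):
        c, r = centers[i : i + chunk], radii[i : i + chunk]
        d = np.abs(
            np.linalg.norm(pts[None, :, :] - c[:, None, :], axis=2) - r[:, None]
        )
        best = max(best, int((d <= eps).sum(axis=1).max()))
    return best


def best_cylinder_inlier_count(
    pts: np.ndarray, normals: np.ndarray, eps: float
) -> int:
    """Max inlier count over every 2-oriented-point cylinder hypothesis."""
    best = 0
    n = len(pts)
    for i, j in combinations(range(n), 2):
        v = np.cross(normals[i], normals[j])
        nv = np.linalg.norm(v)
        if nv <= 1e-6:
            continue
        v = v / nv
        proj = np.eye(3) - np.outer(v, v)
        q1, q2 = proj @ pts[i], proj @ pts[j]
        d1, d2 = proj @ normals[i], proj @ normals[j]
        d1 /= np.linalg.norm(d1)
        d2 /= np.linalg.norm(d2)
        m = (
            (np.eye(3) - np.outer(d1, d1))
            + (np.eye(3) - np.outer(d2, d2))
            + np.outer(v, v)
        )
        rhs = (np.eye(3) - np.outer(d1, d1)) @ q1 + (np.eye(3) - np.outer(d2, d2)) @ q2
        try:
            axis_pt = np.linalg.solve(m, rhs)
        except np.linalg.LinAlgError:
            continue
        r = 0.5 * (np.linalg.norm(q1 - axis_pt) + np.linalg.norm(q2 - axis_pt))
        if r <= 0:
            continue
        rel = pts - axis_pt
        radial = rel - np.outer(rel @ v, v)
        d = np.abs(np.linalg.norm(radial, axis=1) - r)
        best = max(best, int((d <= eps).sum()))
    return best
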