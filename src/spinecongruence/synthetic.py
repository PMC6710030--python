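"""Synthetic posterior-element surface generator.

Stands in for optical topographic imaging of a posterior spinal exposure:
each vertebral level is a labeled point cloud built from a deliberately
minimal parametric composite —

* a **cylindrical laminar arch** (axis cranio-caudal, convex dorsal),
  the source of cylindrical congruence;
* a box-like **spinous-process ridge** on the midline, the feature whose
  base disrupts that congruence in unilateral exposures;
* hemispherical-cap **facet bumps** at the lateral ends, the relief that
  differentiates spinal regions.

Coordinates are mm in a right-handed frame: +y cranio-caudal, +z dorsal,
midline at x = 0.  Every sampler draws from one seeded generator, so all
outputs are bitwise-reproducible per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .errors import SpineCongruenceError
from .shapes import Cylinder, Plane, ShapeModel, Sphere, distance_to_shape

__all__ = [
    "VertebraParams",
    "CohortSpec",
    "REGION_PRESETS",
    "DEFAULT_LEVELS",
    "region_of_level",
    "generate_primitive_patch",
    "generate_vertebra",
    "generate_cohort",
]

#: Fraction of the spinous-process protrusion height counted as its "base".
SP_BASE_HEIGHT_FRACTION = 0.40

#: Clearance shell around a surface that outlier points must stay out of (mm).
OUTLIER_CLEARANCE_MM = 2.0


@dataclass(frozen=True)
class VertebraParams:
    """Geometry and noise of one synthetic vertebral level.

    Lengths in mm, angles in degrees.  ``sp_height = 0`` disables the
    spinous-process ridge entirely; ``facet_count_per_side = 0`` or zero
    facet relief disables the facet bumps.
    """

    arch_radius: float = 14.0
    arch_halfangle: float = 55.0
    arch_axis_tilt: float = 0.0
    arch_length: float = 16.0
    sp_height: float = 12.0
    sp_length: float = 10.0
    sp_base_halfwidth: float = 4.0
    facet_count_per_side: int = 2
    facet_radius_mm: float = 5.0
    facet_height_mm: float = 2.5
    noise_sd: float = 0.15
    outlier_fraction: float = 0.02
    points_per_level: int = 4000
    seed: int = 0

    def __post_init__(self):
        if self.arch_radius <= 0 or self.arch_halfangle <= 0 or self.arch_length <= 0:
            raise SpineCongruenceError("arch dimensions must be positive")
        if not 0 <= self.outlier_fraction < 1:
            raise SpineCongruenceError("outlier_fraction must be in [0, 1)")
        if self.points_per_level < 500:
            raise SpineCongruenceError(
                "points_per_level >= 500 required for stable normal estimation"
            )
        if self.sp_height > 0 and (
            self.sp_length <= 0 or self.sp_base_halfwidth <= 0
        ):
            raise SpineCongruenceError("enabled spinous process needs positive extents")
        if self.sp_base_halfwidth >= self.arch_radius:
            raise SpineCongruenceError("sp_base_halfwidth must be < arch_radius")

    @property
    def sp_enabled(self) -> bool:
        return self.sp_height > 0

    @property
    def facets_enabled(self) -> bool:
        return (
            self.facet_count_per_side > 0
            and self.facet_radius_mm > 0
            and self.facet_height_mm > 0
        )


#: Per-region geometry presets.  Cervical arches are wider and smoother
#: (flatter facets, shorter spinous processes) than thoracolumbar ones —
#: the mechanism behind regional congruence differences.
REGION_PRESETS: dict[str, dict] = {
    "c1": dict(arch_halfangle=65.0, sp_height=3.0, sp_length=6.0,
               facet_height_mm=1.0, facet_radius_mm=4.0),
    "c2": dict(arch_halfangle=60.0, sp_height=10.0,
               facet_height_mm=2.0, facet_radius_mm=4.5),
    "subaxial_cervical": dict(arch_halfangle=60.0, sp_height=8.0,
                              facet_height_mm=1.5, facet_radius_mm=4.0),
    "thoracic": dict(arch_halfangle=45.0, sp_height=12.0,
                     facet_height_mm=2.5, facet_radius_mm=5.0),
    "lumbar": dict(arch_halfangle=40.0, sp_height=14.0,
                   facet_height_mm=3.0, facet_radius_mm=5.5),
    "sacral": dict(arch_halfangle=42.0, sp_height=8.0,
                   facet_height_mm=3.0, facet_radius_mm=5.0),
}

DEFAULT_LEVELS: tuple[str, ...] = tuple(
    [f"C{i}" for i in range(1, 8)]
    + [f"T{i}" for i in range(1, 13)]
    + [f"L{i}" for i in range(1, 6)]
    + ["S1"]
)

#: Parameters subject to inter-specimen multiplicative jitter.
_JITTERED_FIELDS = (
    "arch_radius",
    "arch_halfangle",
    "sp_height",
    "sp_length",
    "sp_base_halfwidth",
    "facet_radius_mm",
    "facet_height_mm",
)


def region_of_level(level: str) -> str:
    """Map a level name (C1..C7, T1..T12, L1..L5, S1) to its region stratum."""
    lv = level.upper()
    if lv == "C1":
        return "c1"
    if lv == "C2":
        return "c2"
    if lv in {f"C{i}" for i in range(3, 8)}:
        return "subaxial_cervical"
    if lv in {f"T{i}" for i in range(1, 13)}:
        return "thoracic"
    if lv in {f"L{i}" for i in range(1, 6)}:
        return "lumbar"
    if lv == "S1":
        return "sacral"
    raise SpineCongruenceError(f"unknown spinal level {level!r}")


@dataclass(frozen=True)
class CohortSpec:
    """A simulated study cohort: specimens x spinal levels.

    ``jitter_sd`` is the standard deviation of a multiplicative log-normal
    jitter applied per specimen to each geometric parameter (0 = identical
    anatomy across specimens).  ``relief_scale`` multiplies facet relief;
    values < 1 emulate the smoother, more congruent surfaces of older
    cadaveric specimens, values > 1 the sharper relief seen in vivo.
    """

    n_specimens: int = 4
    levels: tuple[str, ...] = DEFAULT_LEVELS
    jitter_sd: float = 0.05
    relief_scale: float = 1.0
    base_params: VertebraParams = field(default_factory=VertebraParams)
    seed: int = 0

    def __post_init__(self):
        if self.n_specimens < 1:
            raise SpineCongruenceError("n_specimens must be >= 1")
        if self.jitter_sd < 0:
            raise SpineCongruenceError("jitter_sd must be >= 0")
        for lv in self.levels:
            region_of_level(lv)  # validates names eagerly


# ---------------------------------------------------------------------------
# primitive patches
# ---------------------------------------------------------------------------

def _orthobasis(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing v to a right-handed orthonormal frame."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(v @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(v, ref)
    u /= np.linalg.norm(u)
    w = np.cross(v, u)
    return u, w


def _sample_outliers(
    rng: np.random.Generator,
    n_out: int,
    surface_pts: np.ndarray,
    clearance: float = OUTLIER_CLEARANCE_MM,
    margin: float = 10.0,
    model: ShapeModel | None = None,
) -> np.ndarray:
    """Uniform box outliers at least ``clearance`` mm from the surface.

    Distance is measured to the analytic surface when a model is given,
    else to the sampled surface points (dense sampling makes this a good
    proxy for true surface distance).
    """
    if n_out == 0:
        return np.empty((0, 3))
    lo = surface_pts.min(axis=0) - margin
    hi = surface_pts.max(axis=0) + margin
    tree = None if model is not None else cKDTree(surface_pts)
    out: list[np.ndarray] = []
    need = n_out
    for _ in range(200):  # rejection rounds
        cand = rng.uniform(lo, hi, size=(max(4 * need, 64), 3))
        if model is not None:
            d = distance_to_shape(model, cand)
        else:
            d, _ = tree.query(cand)
        keep = cand[d > clearance]
        out.append(keep[:need])
        need -= len(keep[:need])
        if need == 0:
            break
    if need:
        raise SpineCongruenceError("could not place outliers clear of the surface")
    return np.vstack(out)


def generate_primitive_patch(
    model: ShapeModel,
    n: int,
    noise_sd: float = 0.0,
    outlier_fraction: float = 0.0,
    seed: int = 0,
    patch_extent: float = 40.0,
    with_normals: bool = False,
) -> PointCloud:
    """Sample a bounded patch of a primitive surface plus box outliers.

    ``ceil(n * (1 - outlier_fraction))`` points are drawn uniformly on the
    patch (plane: square of side ``patch_extent``; sphere: the +z
    hemisphere; cylinder: a ±60° arc over an axial extent of
    ``patch_extent``), perturbed by isotropic Gaussian noise; the rest are
    uniform in an expanded bounding box excluding a 2 mm shell around the
    surface.  Labels are ``surface`` / ``outlier``.

    ``with_normals`` attaches analytic (ground-truth) surface normals to
    the surface points — useful for exercising oriented-point estimators
    independently of k-NN normal estimation; outliers get random unit
    vectors.
    """
    if n < 10:
        raise SpineCongruenceError("n must be >= 10")
    if not 0 <= outlier_fraction < 1:
        raise SpineCongruenceError("outlier_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_surface = math.ceil(n * (1 - outlier_fraction))
    n_out = n - n_surface

    if model.kind == "plane":
        u, w = _orthobasis(model.normal)
        origin = -model.offset * model.normal  # plane point closest to origin
        uv = rng.uniform(-patch_extent / 2, patch_extent / 2, size=(n_surface, 2))
        pts = origin + uv[:, :1] * u + uv[:, 1:] * w
    elif model.kind == "sphere":
        # uniform on the +z hemisphere via rejection-free inversion
        z = rng.uniform(0.0, 1.0, n_surface)
        phi = rng.uniform(0.0, 2 * np.pi, n_surface)
        s = np.sqrt(1 - z**2)
        dirs = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
        pts = model.center + model.radius * dirs
    else:
        u, w = _orthobasis(model.direction)
        theta = rng.uniform(-np.pi / 3, np.pi / 3, n_surface)
        axial = rng.uniform(-patch_extent / 2, patch_extent / 2, n_surface)
        radial = np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * w
        pts = model.anchor + axial[:, None] * model.direction + model.radius * radial

    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
    outliers = _sample_outliers(rng, n_out, pts, model=model)
    points = np.vstack([pts, outliers])
    labels = np.array(["surface"] * n_surface + ["outlier"] * n_out, dtype=object)

    normals = None
    if with_normals:
        if model.kind == "plane":
            surf_n = np.tile(model.normal, (n_surface, 1))
        elif model.kind == "sphere":
            surf_n = pts - model.center
            surf_n /= np.linalg.norm(surf_n, axis=1, keepdims=True)
        else:
            rel = pts - model.anchor
            surf_n = rel - np.outer(rel @ model.direction, model.direction)
            surf_n /= np.linalg.norm(surf_n, axis=1, keepdims=True)
        out_n = rng.normal(size=(n_out, 3))
        out_n /= np.linalg.norm(out_n, axis=1, keepdims=True)
        normals = np.vstack([surf_n, out_n]) if n_out else surf_n

    return PointCloud(points=points, normals=normals, labels=labels)


# ---------------------------------------------------------------------------
# vertebra
# ---------------------------------------------------------------------------

def _allocate(total: int, weights: list[float]) -> list[int]:
    """Deterministic proportional allocation (largest remainder)."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    raw = w * total
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts.tolist()


def generate_vertebra(params: VertebraParams) -> PointCloud:
    """One labeled posterior-element surface.

    Surface components are sampled with point counts proportional to
    their areas; arch points under the spinous-process footprint and the
    facet-cap bases are removed so the ridge and bumps replace, not
    overlay, the arch.  Gaussian sensor noise and box outliers are applied
    last.  Labels partition the cloud into {left,right}_hemilamina,
    sp_base, sp_tip, facet and outlier.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    R = p.arch_radius
    alpha = math.radians(p.arch_halfangle)
    L = p.arch_length
    w = p.sp_base_halfwidth
    h = p.sp_height
    l = p.sp_length
    z_apex = R

    sp_on = p.sp_enabled
    facets_on = p.facets_enabled
    z_arch_at_w = math.sqrt(R**2 - w**2)
    wall_height = h + (R - z_arch_at_w) if sp_on else 0.0

    # facet cap geometry: spherical cap of height fh carved from a sphere
    # of radius fr, protruding dorsally at the lateral arch edge
    fr, fh = p.facet_radius_mm, p.facet_height_mm
    facet_centers: list[np.ndarray] = []
    if facets_on:
        fh = min(fh, fr)  # cap height cannot exceed sphere radius
        x_edge = R * math.sin(alpha)
        z_edge = R * math.cos(alpha)
        ys = np.linspace(-L / 2 + fr, L / 2 - fr, p.facet_count_per_side)
        for side in (-1.0, 1.0):
            for y_c in ys:
                facet_centers.append(
                    np.array([side * x_edge, y_c, z_edge - (fr - fh)])
                )
    cap_base_r = math.sqrt(max(fr**2 - (fr - fh) ** 2, 0.0)) if facets_on else 0.0

    # component areas drive the sampling allocation
    area_arch = 2 * R * alpha * L
    if sp_on:
        area_arch -= 2 * R * math.asin(w / R) * l  # footprint removed
    area_walls = 2 * l * wall_height if sp_on else 0.0
    area_top = 2 * w * l if sp_on else 0.0
    area_ends = 2 * (2 * w) * (h + (R - z_arch_at_w) / 2) if sp_on else 0.0
    area_caps = len(facet_centers) * 2 * math.pi * fr * fh if facets_on else 0.0

    n_total = p.points_per_level
    n_out = int(round(n_total * p.outlier_fraction))
    n_surface = n_total - n_out
    comps = ["arch", "walls", "top", "ends", "caps"]
    counts = dict(
        zip(comps, _allocate(n_surface, [area_arch, area_walls, area_top, area_ends, area_caps]))
    )

    all_pts: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []

    def in_sp_footprint(x, y):
        return sp_on & (np.abs(x) <= w) & (np.abs(y) <= l / 2)

    def in_facet_base(x, y):
        if not facets_on:
            return np.zeros_like(x, dtype=bool)
        hit = np.zeros_like(x, dtype=bool)
        for c in facet_centers:
            hit |= (x - c[0]) ** 2 + (y - c[1]) ** 2 <= cap_base_r**2
        return hit

    # -- laminar arch (rejection-sample around removed footprints)
    need = counts["arch"]
    arch_pts = []
    while need > 0:
        m = max(2 * need, 64)
        theta = rng.uniform(-alpha, alpha, m)
        y = rng.uniform(-L / 2, L / 2, m)
        x = R * np.sin(theta)
        z = R * np.cos(theta)
        keep = ~in_sp_footprint(x, y) & ~in_facet_base(x, y)
        pts = np.column_stack([x, y, z])[keep][:need]
        arch_pts.append(pts)
        need -= len(pts)
    arch = np.vstack(arch_pts) if arch_pts else np.empty((0, 3))
    arch_labels = np.where(arch[:, 0] < 0, "left_hemilamina", "right_hemilamina")
    all_pts.append(arch)
    all_labels.append(arch_labels.astype(object))

    # -- spinous-process ridge: side walls, top, end walls
    if sp_on:
        z_top = z_apex + h
        sp_pts = []
        nw = counts["walls"]
        side = rng.choice([-1.0, 1.0], nw)
        yw = rng.uniform(-l / 2, l / 2, nw)
        zw = rng.uniform(z_arch_at_w, z_top, nw)
        sp_pts.append(np.column_stack([side * w, yw, zw]))

        nt = counts["top"]
        sp_pts.append(
            np.column_stack(
                [
                    rng.uniform(-w, w, nt),
                    rng.uniform(-l / 2, l / 2, nt),
                    np.full(nt, z_top),
                ]
            )
        )

        ne = counts["ends"]
        end_pts = []
        need = ne
        while need > 0:
            m = max(2 * need, 64)
            xe = rng.uniform(-w, w, m)
            ze = rng.uniform(z_arch_at_w, z_top, m)
            keep = ze >= np.sqrt(R**2 - xe**2)  # above the arch surface
            ye = rng.choice([-l / 2, l / 2], m)
            pts = np.column_stack([xe, ye, ze])[keep][:need]
            end_pts.append(pts)
            need -= len(pts)
        sp_pts.append(np.vstack(end_pts) if end_pts else np.empty((0, 3)))

        sp = np.vstack(sp_pts)
        protrusion = sp[:, 2] - np.sqrt(R**2 - sp[:, 0] ** 2)
        sp_labels = np.where(
            protrusion <= SP_BASE_HEIGHT_FRACTION * h, "sp_base", "sp_tip"
        )
        all_pts.append(sp)
        all_labels.append(sp_labels.astype(object))

    # -- facet caps: points on each sphere with dorsal offset >= fr - fh
    if facets_on and counts["caps"] > 0:
        per_cap = _allocate(counts["caps"], [1.0] * len(facet_centers))
        for c, m in zip(facet_centers, per_cap):
            # uniform on the cap via inversion on the z-offset
            zo = rng.uniform(fr - fh, fr, m)
            phi = rng.uniform(0, 2 * np.pi, m)
            s = np.sqrt(np.maximum(fr**2 - zo**2, 0.0))
            pts = c + np.column_stack([s * np.cos(phi), s * np.sin(phi), zo])
            all_pts.append(pts)
            all_labels.append(np.full(m, "facet", dtype=object))

    points = np.vstack(all_pts)
    labels = np.concatenate(all_labels)

    if p.arch_axis_tilt != 0.0:
        t = math.radians(p.arch_axis_tilt)
        rot = np.array(
            [[1, 0, 0], [0, math.cos(t), -math.sin(t)], [0, math.sin(t), math.cos(t)]]
        )
        points = points @ rot.T

    if p.noise_sd > 0:
        points = points + rng.normal(0.0, p.noise_sd, size=points.shape)

    if n_out > 0:
        outliers = _sample_outliers(rng, n_out, points)
        points = np.vstack([points, outliers])
        labels = np.concatenate([labels, np.full(n_out, "outlier", dtype=object)])

    return PointCloud(points=points, labels=labels)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _jittered(base: VertebraParams, rng: np.random.Generator, sd: float) -> VertebraParams:
    if sd == 0:
        # still consume the draws so cloud seeds stay aligned across jitter settings
        rng.normal(0.0, 1.0, len(_JITTERED_FIELDS))
        return base
    factors = np.exp(rng.normal(0.0, sd, len(_JITTERED_FIELDS)))
    updates = {
        name: getattr(base, name) * f for name, f in zip(_JITTERED_FIELDS, factors)
    }
    # a disabled spinous process stays disabled
    if not base.sp_enabled:
        updates["sp_height"] = 0.0
    return replace(base, **updates)


def generate_cohort(spec: CohortSpec) -> dict[tuple[str, str], PointCloud]:
    """One cloud per (specimen, level), keyed ``(\"S1\", \"C1\")`` etc.

    Level geometry comes from :data:`REGION_PRESETS`; specimen-to-specimen
    variation is multiplicative jitter on the geometric parameters.  The
    cloud-sampling seed depends on (cohort seed, level) only, so with
    ``jitter_sd = 0`` all specimens share identical per-level clouds.
    """
    clouds: dict[tuple[str, str], PointCloud] = {}
    for s_idx in range(spec.n_specimens):
        specimen = f"S{s_idx + 1}"
        jit_rng = np.random.default_rng(
            (spec.seed * 1_000_003 + 7919 * (s_idx + 1)) % (2**31 - 1)
        )
        for l_idx, level in enumerate(spec.levels):
            preset = dict(REGION_PRESETS[region_of_level(level)])
            preset["facet_height_mm"] = preset["facet_height_mm"] * spec.relief_scale
            cloud_seed = (spec.seed * 1_000_003 + 104_729 * (l_idx + 1)) % (2**31 - 1)
            base = replace(spec.base_params, **preset, seed=cloud_seed)
            params = _jittered(base, jit_rng, spec.jitter_sd)
            clouds[(specimen, level)] = generate_vertebra(params)
    return clouds
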