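# Methods

## The problem

Surface-based image-to-patient registration (for example structured-light
scanning of an exposed spine, aligned to pre-operative CT with an
iterative closest-point algorithm) relies on the exposed surface having
geometrically *unique* shape. If the surface is well approximated by a
symmetric primitive — a cylinder, a sphere, or a plane — there is a whole
family of rigid motions that leave the surface-to-surface distance nearly
unchanged: rotation about and translation along a cylinder's axis,
arbitrary rotation about a sphere's centre, in-plane translation and
rotation for a plane. ICP can then converge to a wrong but
low-residual pose, i.e. a *successful-looking but inaccurate*
registration. This package quantifies that risk, called geometric
congruence, for posterior spinal exposures.

## Congruence metric

Each exposure point cloud (mm units) is fitted with each of the three
primitives by random sample consensus:

* minimal samples: 3 points (plane), 4 points (sphere), 2 *oriented*
  points (cylinder: axis = n₁×n₂, axis position from the least-squares
  intersection of the projected normal lines, radius = mean projected
  distance). These are the standard efficient estimators from the
  primitive-detection literature; a 5-point unoriented cylinder
  estimator could be swapped in behind the same interface.
* exactly `iterations` (default 100) hypothesis draws per fit, sampling
  point indices without replacement within a draw; degenerate samples
  (collinear triple, coplanar quadruple, near-parallel normals) consume
  an iteration, keeping the draw count exact;
* inlier criterion: unsigned Euclidean point-to-surface distance ≤ the
  maximum inlier error ε (default 0.5 mm) — absolute distance, not
  squared or signed, because ε is specified in mm;
* winner: most inliers, ties broken by lower inlier RMSE, then by
  earlier iteration index — a total order, so results are reproducible;
* polish: the winner is refined once by least squares on its inlier set
  (plane closed-form via principal directions; sphere/cylinder
  trust-region least squares started at the winner) and the inlier mask
  is recomputed once against the refined model. A single
  refine+re-mask, rather than iterated consensus, keeps the procedure
  deterministic and commensurate with a 100-iteration budget. If
  refinement fails to reduce the RMSE it is discarded with a warning.

The congruence score is the **inliers-to-points ratio (ITPR)** — the
fraction of the cloud within ε of the fitted surface. Higher ITPR on
any primitive means higher congruence and higher registration-ambiguity
risk. The fit also reports the inlier RMSE; the published definition of
cloud-to-shape RMSE is ambiguous about inlier restriction, so an
all-points variant (`rmse_all`) is reported alongside, with inlier RMSE
primary.

Normals, needed only by the cylinder estimator, come from local PCA of
the `k = 20` nearest neighbours (least-variance direction), oriented to
the +z hemisphere with ties broken toward +y then +x. The orientation
convention is arbitrary but fixed; the cylinder estimator is invariant
to normal signs. `k = 20` assumes the default sampling density (several
thousand points per level); sparse clouds warrant a smaller `k`.

### Choosing ε: CoV-RMSE sensitivity

ITPR depends on the user-specified ε. To select it, `cov_rmse` runs
`repeats` (default 20) independent RANSAC fits and returns the
coefficient of variation (sample SD / mean — coefficient of variation is
mean-adjusted by definition) of the RMSE across repeats; `select_epsilon`
averages this over clouds and shapes for each ε in {0.1, 0.5, 1.0,
2.0} mm and picks the argmin, ties to the smaller ε. All-identical or
all-zero RMSE gives CoV 0 by convention. The published analysis selected
ε = 0.5 mm on scanned anatomy; on synthetic cohorts only the selection
*structure* (the argmin rule) is checkable, since the underlying CoV
values of the original data were never printed.

## Exposure reconstructions and contrasts

From each labeled surface map three exposures are reconstructed,
preserving point order:

* **Group A** — all non-outlier points (bilateral hemilaminae plus
  spinous process);
* **Group B** — one side (sign of x about the midline) plus the
  ipsilateral spinous-process *base* points;
* **Group C** — one side excluding every spinous-process point.

Both sides contribute B and C records (pooled, not averaged — the
alternative per-level averaging was considered and pooling chosen as the
simpler convention). Unlabeled clouds can be reconstructed by supplying
a midline plane and a spinous-process band half-width; within the band
the lowest 40% of the dorsal span counts as base.

A study run fits all three shapes to the five reconstructions of every
(specimen, level) cell, each fit with a deterministic per-record seed
(base seed offset per shape: plane +1, sphere +2, cylinder +3), and
summarises:

* mean ± sample SD ITPR by (region, group, shape), regions C1, C2,
  subaxial cervical C3–C7, thoracic T1–T12, lumbar L1–L5, sacral S1;
* per-level Group B−A and C−B contrasts (mean ± SD across specimens,
  sides averaged within specimen first);
* percent reductions `100·(pre − post)/pre`, reported to one decimal:
  *laterality* (unilateral B+C pooled → bilateral A) and
  *spinous-process inclusion* (C → B). ITPR summaries print to three
  decimals.

Cells whose reconstruction or fit fails are logged and skipped; a run
aborts if more than 10% of cells fail.

## Statistics

`anova_oneway` is the classic fixed-effects one-way ANOVA from explicit
sums of squares; `tukey_hsd` computes studentized-range statistics with
the Tukey–Kramer standard error for unbalanced groups, with tail
probabilities from the studentized-range distribution (for k = 2 the
adjusted p equals the pooled two-sample t-test p, which the test suite
verifies to 1e-6); `levene` is the classic mean-centred Levene test (an
ANOVA on absolute deviations; `center="median"` gives the
Brown–Forsythe variant). Significance defaults to α = 0.05.
Hierarchical mixed-effects adjustment for specimen is out of scope;
stratifying by specimen and running per-stratum ANOVA is the documented
approximation.

## The synthetic cohort generator

Real optical surface scans are replaced by a deliberately minimal
parametric composite whose every component maps to one finding:

* **laminar arch** — a cylinder segment (radius 14 mm, swept
  ±`arch_halfangle` about the dorsal apex, axis cranio-caudal) — the
  source of cylindrical congruence;
* **spinous-process ridge** — a box ridge on the midline (height
  12 mm, length 10 mm, half-width 4 mm) replacing arch points under its
  footprint; its *base* is the lowest 40% of the protrusion height.
  The ridge is what disrupts congruence when included in a unilateral
  exposure;
* **facet bumps** — spherical caps at the lateral arch edges (2 per
  side, radius 5 mm, height 2.5 mm), the relief that differentiates
  regions: cervical presets are wider-arched and flatter-faceted
  (higher congruence), lumbar presets narrower with taller relief.

Point counts are allocated across components proportionally to surface
area (largest-remainder rounding, deterministic), isotropic Gaussian
sensor noise (σ = 0.15 mm, in the range of structured-light scanner
noise) is added last, and 2% of points are replaced by uniform box
outliers kept at least 2 mm clear of the surface. The default density
is 4000 points per level — enough for stable k = 20 normal estimation.
Cohorts (default 4 specimens × 25 levels C1–S1) apply per-region presets
plus multiplicative log-normal jitter (sd 0.05) to each specimen's
geometric parameters; cloud sampling seeds depend only on (cohort seed,
level), so zero jitter reproduces identical anatomy across specimens.
A `relief_scale` factor emulates cohort-level surface character
(smoother relief for older cadaveric specimens, sharper in vivo); it is
a modelling knob, not an anatomical claim.

What the generator does *not* emulate: real vertebral shape variation
(no statistical shape model), osteophytes, soft-tissue remnants,
scanner-specific noise anisotropy, occlusion or viewpoint effects.
Consequently the *absolute* ITPR values of scanned anatomy are not
reproducible here, and no test asserts them; what the synthetic cohort
does support is the qualitative structure — bilateral exposures least
congruent, spinous-process inclusion reducing congruence, cervical
levels more cylindrical than lumbar — which is exactly what the
acceptance suite asserts.

## Numerical choices and degenerate inputs

* Degeneracy guards: plane, cross-product norm < 1e-9 × scale; sphere,
  linear-system determinant < 1e-9 × scale³; cylinder, ‖n₁×n₂‖ ≤ 1e-6.
  An *exactly* planar cloud therefore admits no sphere or cylinder
  hypothesis at all (every quadruple coplanar, all normals parallel) and
  the fit reports "no valid hypothesis"; near-planar clouds yield the
  expected large-radius surrogate fits.
* Model canonicalisation: unit normals/axes stored with the
  lexicographically larger of {v, −v}; the cylinder anchor is the axis
  point nearest the origin. Equality of fitted models is therefore
  well defined.
* Refinement uses scipy's trust-region least squares with the winner as
  the initial iterate and a 200-evaluation budget; the cylinder
  parametrisation (anchor, unnormalised direction, radius) is
  gauge-redundant, which the solver tolerates, and the result is
  re-canonicalised.
* Problem sizes: the shipped study configuration (4 × 25 levels,
  4000 points per level, 100 iterations, ε = 0.5 mm) runs in about a
  minute on one CPU; CoV-RMSE repeats default to 20 for analyses and 5
  in the bundled acceptance script's sensitivity pass, which is enough
  to rank the ε grid stably at these noise levels.

## Known limitations

* The synthetic generator is a geometric caricature; regional presets
  are illustrative, not measured anatomy.
* RANSAC with a fixed 100-iteration budget is near-optimal, not
  optimal; the test suite checks ≥ 95% of the exhaustive
  minimal-sample optimum on small clouds.
* Mixed-effects modelling across specimens/patients is not implemented;
  the univariate statistics treat records as independent.
* Only plane, sphere and cylinder congruence is scored; other ambiguous
  geometries (e.g. surfaces of revolution generally) are out of scope.
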