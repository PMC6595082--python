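# Methods

## Problem and model

`longivol` measures the longitudinal volume change of a compact brain
structure (the motivating case is the hippocampus in aging and dementia)
from two inputs that any registration tool can produce: a binary baseline
segmentation and a dense displacement field u(x) mapping baseline world
coordinates to follow-up coordinates. The atrophy rate is expressed as
percentage volume change,

    PVC = (V_FU − V_BL) / V_BL × 100,

negative for shrinkage. Two independent routes estimate V_FU:

1. **Mesh route (primary).** The baseline segmentation is converted once to
   a closed triangle surface by marching cubes at iso-level 0.5 and every
   subsequent transform moves the vertices directly — rigid/affine maps are
   applied exactly to the vertex coordinates, non-linear fields by
   trilinear sampling of u at each vertex. The enclosed volume is the sum
   of signed tetrahedra (origin, v0, v1, v2) over the faces, which by the
   divergence theorem is exact for any closed, consistently oriented
   surface and invariant to translation. Because the surface, not the
   label image, carries the volume, no resampling/interpolation of labels
   ever occurs between time points.
2. **Jacobian route (consistency check).** V_FU = Σ det(I + ∂u/∂x) · v_vox
   over the baseline mask voxels; det(I + ∂u/∂x) is the local volume
   scaling of the deformation.

For a smooth invertible field the two routes estimate the same integral
from different discretizations (iso-surface region vs. voxelized mask;
vertex-sampled field vs. finite-difference gradients), so their difference
is a meaningful internal quality check. On the synthetic battery at 1 mm
spacing the routes agree to < 0.03 percentage points, comfortably inside
the 0.1-point acceptance tolerance, and the discrepancy shrinks roughly
linearly with spacing.

## Numerical choices

- **Iso-level and smoothing.** Binary masks are meshed at 0.5, the unbiased
  midpoint, with no pre-smoothing or decimation; the marching-cubes variant
  is scikit-image's Lewiner table, whose degenerate-case resolution is
  absorbed by the stated tolerances.
- **Padding.** One zero-voxel layer is always added before extraction so
  that foreground touching the array boundary still yields a closed
  surface (logged when it happens); a clipped open mesh is never returned.
- **Orientation.** Meshes are re-wound to outward orientation (positive
  signed volume) after extraction and after orientation-reversing affines.
  A negative total signed volume at measurement time is reported by
  magnitude with a logged warning, since downstream PVC needs V > 0.
- **Derivative stencil.** The Jacobian uses central differences in
  voxel-index space, second-order one-sided at grid edges, mapped to world
  units by the chain rule ∂u/∂x = (∂u/∂index)·A₃⁻¹ with A₃ the 3×3 affine
  block. The chain rule is exact for any invertible grid affine, so
  oblique and even sheared grids are supported without a special case
  (exactness on linear fields is tested on a rotated anisotropic grid).
  Non-positive determinants (folding) are counted and logged, never
  silently clipped.
- **Out-of-domain behaviour.** Vertices outside the field's bounding box
  receive zero displacement with a logged count; more than 1% of a mesh
  outside the domain is an error.
- **Degenerate statistics inputs.** An all-identical ANOVA table returns
  F = 0 with Tukey p = 1 (the 0/0 limit taken as "no evidence of any
  difference"); a zero between-group effect makes the sample-size formula
  diverge and is an error.

## Evaluation statistics

- **Exclusion rule.** Records with |PVC| strictly greater than 25% are
  flagged as implausible (segmentation/registration failure). Flagging
  never deletes: each analysis applies its own mask, so outlier handling
  stays auditable. Strict inequality means −25.0 exactly is retained.
- **Left/right averaging.** Subject-scan atrophy is the mean of the left
  and right structure PVCs; a subject-scan missing either unflagged side
  is omitted (logged) rather than imputed.
- **D_Ave.** Reproducibility and agreement are both the RMS difference of
  paired PVCs: across A/B back-to-back replicates (true change zero, so
  D_Ave is pure method noise) or across methods on the pooled A+B records.
- **Group ANOVA.** Default mode "pooled" enters each subject's A and B
  replicates as separate observations in a one-way ANOVA — with 80
  subjects × 2 scans in 3 groups this yields the F(2, 157) degree-of-
  freedom pattern, matching how the reference analysis's dfs come out. A
  "mixed" mode (group × scan split-plot via pingouin, scan within-subject)
  is provided as the statistically principled alternative; it uses the
  between-subject error term (df = subjects − groups). Tukey HSD adjusted
  pairwise p-values accompany both.
- **Power analysis.** Cohen's d uses the *unweighted* pooled SD,
  σ_pooled = sqrt((σ₁² + σ₂²)/2); required per-group sample size is the
  normal-approximation N = 2(z_{α/2} + z_{1−β})²/d², rounded to the
  *nearest* integer. Both conventions were fixed by checking which
  reproduces the published effect-size table from its printed group
  statistics: df-weighted pooling and ceiling rounding each break at least
  one printed entry, unweighted pooling plus nearest rounding reproduce
  every CTRL–AD sample size. Because the printed means/SDs are rounded to
  2–3 decimals, recomputed d values can differ from the printed ones by up
  to ~0.01 (e.g. 0.9653 vs a printed 0.96), and CTRL–MCI sample sizes —
  large because the effect is small — by a few subjects; the reproduction
  asserts exactness only where printed precision suffices.

## Synthetic data: what it emulates, and what it does not

The generator produces three layers of input, all deterministic per seed.

**Shapes.** Digitized ellipsoids (default semi-axes 12 × 8 × 6 mm ≈
2413 mm³) and radially perturbed blobs stand in for hippocampus
segmentations; the 2000–4000 mm³ default range is a literature-typical
convention, since absolute volumes are not part of the reference summary
statistics. Digitization samples voxel *centers* on a cell-centered grid
(centers offset half a spacing from the shape's symmetry planes): placing
the analytic boundary exactly on sample points is a degenerate alignment
that inflates surface error (−2.9% vs −0.65% mesh-volume error at 1 mm for
the default ellipsoid), and real segmentations have no such alignment.

**Fields.** Five analytic families (zero, translation, uniform scale,
radial Gaussian contraction, random smooth Gaussian bumps) with documented
invertibility bounds (contraction amplitude k < 0.9; summed gradient bound
< 0.5 for the bump superposition). Ground-truth regional PVC is
closed-form where it exists and otherwise a quadrature of the analytic
determinant over a 4× refined digitization of the shape (stable to
< 0.05 points against 8× refinement).

**Cohorts.** Per subject i in group g: true PVC v_i ~ N(μ_g, σ_true) with
σ_true² = σ_g² − σ_ε²; each scan replicate observes v_i + ε,
ε ~ N(0, σ_ε); left/right split antisymmetrically as value ± δ,
δ ~ N(0, 0.5%). This is the simplest model that simultaneously reproduces
the reference per-group SDs (pooled observation variance is σ_g² by
construction) and a target test–retest distance (E[D_Ave] = √2·σ_ε). The
per-method default σ_ε is the published D_Ave/√2, capped at 0.9× the
smallest group SD — for poorly reproducible methods (e.g. manual
outlining) the additive-Gaussian model cannot attain the published D_Ave
without exceeding the group spread, which is itself informative: real
replicate noise there is heavy-tailed and correlated with failures, not
i.i.d. Gaussian. Optional outlier injection (uniform beyond the ±25%
threshold) exercises the exclusion path and is off by default.

What passing synthetic tests does **not** show: robustness to real
segmentation topology (handles, touching structures), to registration
failure modes (folding, boundary drift), to field discretization coarser
than the segmentation, or to non-Gaussian cohort structure. The statistics
reproduction uses printed summary inputs and therefore validates the
formulas and conventions, not the upstream measurement chain on clinical
data.

## Problem sizes

Default analyses use 1 mm isotropic grids of roughly 30–40 voxels per axis
(half-spacing refinements where convergence is asserted), ten-fixture
route-equivalence batteries, and 50 seed replicates of the 80-subject
cohort for parameter-recovery checks; these sizes were chosen so every
property is measured with comfortable margin while the whole suite stays
interactive.

## Known limitations

- The mesh route assumes the field is smooth at the vertex spacing;
  severely folded fields are only detected (negative-Jacobian count), not
  corrected.
- Jacobian integration uses the voxelized mask, so its region differs from
  the iso-surface region by a sub-voxel surface layer; the residual
  route difference reflects that mismatch and bounds achievable agreement.
- The inverse problem (follow-up→baseline fields) is out of scope; fields
  must be tagged with their direction and only baseline→follow-up fields
  are consumed.
- `simulate` models measurement noise at the PVC level; it does not
  simulate images, scanner effects, or segmentation errors.
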