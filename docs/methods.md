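# Methods

## The model

Each voxel of the contoured primary tumor is one observation with a
single covariate, its pre-treatment tumor-to-muscle ratio (TMR), and a
binary response: whether the voxel lies inside the recurrent-tumor
contour mapped into the pre-treatment frame. The pooled model is plain
logistic regression,

    logit P(overlap | TMR = t) = a + b·t,

fitted by maximum likelihood over all voxels of an analysis pool: either
the recurrent patients only, or the whole series with every voxel of the
non-recurrent patients added to the non-overlap group. The quantities of
clinical interest are derived from the fit: the odds ratio per unit TMR,
exp(b); the TMR at a chosen recurrence probability,
t(p) = (logit p − a)/b, which is what a dose-painting protocol would
threshold on; and the ROC area of TMR as a voxel classifier.

**Assumptions.** Voxels are treated as independent observations. This is
the analysis's explicit working assumption and it is exactly what the
independent-mode synthetic generator reproduces, so parameter recovery on
phantoms is unbiased. Real tumors are spatially coherent; under
correlation the point estimates remain consistent but the pooled-voxel
standard errors are too small. The contiguous sampling mode exists to
quantify this: it produces recurrence regions with the same marginal
logistic law but strong spatial correlation, under which the nominal 95%
Wald intervals undercover. No clustered-by-patient or mixed-effects
model is provided, matching the scope of the original pooled analysis.

## Registration

Recurrence-time images are aligned to the pre-treatment frame with a
proper rigid motion (no scaling or shear) fitted to paired anatomical
landmarks — bone landmarks in practice, since bone is unaffected by
tumor response. The fit is the closed-form Kabsch least-squares solution:
SVD of the landmark cross-covariance with the determinant of the rotation
corrected to +1, so a reflection-optimal configuration still yields a
proper rotation. Landmark-based fitting was chosen over intensity-based
registration to make the step deterministic and exactly testable; the
residual landmark RMSD is logged per patient as the quantitative
counterpart of a visual registration check. Degenerate configurations
(fewer than three pairs, collinear points) raise an explicit error.

Transforms map moving → fixed (`x_fixed = R x_moving + t`). Resampling
pulls target voxel centers back through the inverse transform and
samples the source grid: trilinearly for SUV volumes (smooth
intensities, never negative), nearest-neighbor for masks (binary values
preserved; a sub-voxel shift changes a mask's cardinality by at most its
surface voxel count). Out-of-field voxels become 0.

Grids are axis-aligned with 0-based (x, y, z) indices; a voxel center
sits at `origin + index · spacing`. The default spacing is the 1 × 1 ×
2 mm analysis grid on which all published voxel counts live, not the
scanner's native reconstruction grid; both are configurable.

## TMR normalization and the 0–255 data files

The muscle reference is the mean over four 1-cm-radius spheres on the
posterior cervical muscles of each sphere's maximum SUV; sphere
membership is voxel-center distance ≤ radius in world mm. TMR is the
voxel SUV divided by this reference, making it invariant to global SUV
rescaling. Voxels outside the analyzed contour are excluded by setting
them to NaN — a sentinel deliberately distinct from TMR 0, so the
exported grayscale convention "0 = outside the ROI" can never collide
with a real measurement.

The original analysis exchanged images as 256-level grayscale data
files. `quantize_255` maps a TMR window linearly onto gray levels 1–255
(clamped, monotone) with 0 reserved for excluded voxels, and
`export_datafile` writes per-axial-slice integer matrices zero-padded to
a square matrix (default 512 × 512), round-tripping losslessly. The
default window (0, 4) covers every ratio the analysis produces with
headroom; the original grayscale scaling is not stated anywhere, which
is also why all statistics default to the *continuous* TMR values — the
quantized path exists for fidelity and is an option, not the default.
At the default window the quantization step is 4/254 ≈ 0.016 TMR, so
fits on quantized data differ from continuous fits by less than the
sampling error of any realistic pool.

## Statistics

**Mann-Whitney U** uses mid-ranks throughout. For small problems
(n₁·n₂ ≤ 400) the two-sided p-value is exact: the null distribution of
the group rank sum under relabeling is built by dynamic programming over
(subset size, subset sum) on doubled mid-ranks, which is correct in the
presence of ties (subset counts up to C(40, 20) ≈ 1.4 × 10¹¹ are exactly
representable in double precision); p = 2·min(lower tail, upper tail),
capped at 1. Larger problems use the normal approximation with
tie-corrected variance and continuity correction. Two groups of entirely
identical values make the test vacuous: p = 1 with a warning, not a
crash. All tests are two-sided at the 0.05 level with no
multiple-testing correction, matching the original analysis.

**Logistic regression** is fitted by iteratively reweighted least
squares (Newton-Raphson), converging when the largest absolute score
falls below 1e-8 or the parameter step below 1e-10, capped at 100
iterations; the covariance is the inverse observed information at the
optimum. With a single covariate, complete and quasi-complete separation
are detected exactly from the ordering of the two groups' TMR ranges
before iterating, and a diverging linear predictor (|η| > 300) during
iteration raises the same hard error — separated or non-converged fits
are never silently reported. Non-convergence carries the iteration
trace.

**Intervals.** The odds-ratio CI is Wald on the log-odds scale,
exp(b ± 1.96·SE(b)) — with SE(b) = 0.0315 this reproduces the published
interval 4.87–5.51 around 5.18 to two decimals, which is how that SE
back-solves. The CI for t(p) uses the delta method on the ratio
(logit p − a)/b with gradient (−1/b, −t/b); the method behind the
published threshold intervals is unstated, and the delta method is this
package's choice.

**ROC.** The curve is swept over all distinct TMR values
(scikit-learn's `roc_curve` with no intermediate-point dropping) and the
AUC is the trapezoidal area. With mid-rank tie handling this equals
U/(n₁·n₀) identically; the identity is asserted to 1e-12 in the tests as
a cross-check between the two independent computations.

**Voxel bookkeeping.** Classification guarantees
n_ovl + n_non_ovl = |ROI_pri| per patient, and pooled counts are sums of
per-patient counts. Recurrence voxels falling outside the primary
contour are counted and either clipped (default — in the published
cohort the recurrent-contour counts equal the overlap counts, implying
containment) or rejected, by policy. `count_above` uses strict
inequality (TMR > threshold). Medians use the standard order statistic,
averaging the two central values for even n (required to reproduce a
46.5-month median follow-up from 12 patients).

## The synthetic generator

The generator emulates the *statistical* structure the analysis rests
on, not PET physics: no point-spread function, scatter, reconstruction
or pharmacokinetic uptake model. One phantom is an axis-aligned grid
(default 96 × 96 × 60 voxels at 1 × 1 × 2 mm) holding:

* an ellipsoidal primary tumor — default radii (20, 18, 15) mm ≈ 11,300
  voxels, near the published cohort median of 10,954, with per-patient
  log-normal size scaling (σ = 0.3, clipped to [0.45, 1.5]) spanning
  roughly 1,000–38,000 voxels, matching the published range
  1,220–39,955;
* an ellipsoidal hypoxic core strictly inside it (containment checked
  both analytically on the surface and on the voxelized masks);
* SUV levels background 1.0, tumor 1.2, hypoxic 2.4 with additive
  Gaussian noise (SD 0.1) clipped at zero. Against the resulting muscle
  reference of ≈ 1.3 these give a mean in-tumor TMR just below 1 and a
  hypoxic-core TMR near 1.9 — the regime of the published cohort (mean
  overlap-voxel TMR 1.01, mean maximum TMR ≈ 1.9). Ellipsoids were
  chosen for their closed-form volumes, which give an analytic oracle
  for voxel counts;
* four muscle reference spheres (radius 10 mm) well clear of the tumor;
* a recurrence region drawn from the logistic law with default
  parameters b* = ln 5.18 and a* = −1.88·ln 5.18 ≈ −3.092 — the
  published curve's anchors — in one of two modes. *Independent* draws
  each in-tumor voxel Bernoulli(p(TMR)): the analysis's own assumption,
  so recovery is unbiased. *Contiguous* thresholds a smoothed Gaussian
  field (4 mm kernel, standardized to normal marginals) at the per-voxel
  probability, yielding coherent regions with approximately the same
  marginal law, for robustness checks only. An all-empty draw is
  rejected as degenerate (a recurrent patient must recur somewhere); a
  saturated law that selects the whole tumor is returned as-is, since it
  still satisfies containment and pools correctly with other patients.
  The published study never states recurrence-region morphology beyond
  voxel counts (153–4,410), so the contiguous mode's shape statistics
  are a free design choice;
* optional rigid misalignment of the recurrence-time set (defaults:
  rotation up to 5°, translation up to 3 mm per axis — the scale bone-
  anchored setups leave) with landmarks to register it back.

Everything is seeded: identical configs give bit-identical phantoms,
and a fixed cohort seed gives byte-identical JSON reports.

What passing phantom tests does *not* show about real data: phantoms
have no reconstruction artifacts, no partial-volume effect at the tumor
rim, no contouring variability, and (in independent mode) no spatial
correlation — so real-data standard errors will be optimistic, and
registration on real anatomy is harder than on noiseless landmarks.

Synthetic cohort covariates mirror the published cohort: 9 recurrent /
12 non-recurrent patients, recurrence times log-normal with median 11
months, follow-up uniform on 37–61 months, and planned-dose summaries
(D_mean, D_min) drawn around the published group means — the study
prints only group-level dose statistics, so per-patient dose comparisons
can only ever be exercised on synthetic values.

## Problem sizes used in the checks

The simulation-based checks run at desk scale: ground-truth parameter
recovery uses 200 replicates of 20,000 voxels (about the voxel count of
two patients); the AUC/U identity uses 1,000 two-group toys of up to 25
voxels per group; end-to-end cohort tests use compact 64 × 64 × 40
phantoms. These sizes put Monte-Carlo error well below the tolerances
being asserted while keeping the whole suite fast.

## Known limitations

* Pooled-voxel inference ignores within-patient correlation; intervals
  are anti-conservative on spatially coherent data (quantified by the
  contiguous mode).
* Rigid, landmark-based registration only; no deformable registration,
  although real anatomy changes between baseline and recurrence.
* Whether the original regression ran on continuous TMR or on the 0–255
  quantized values is not stated; this package defaults to continuous
  and offers the quantized path.
* Dose comparisons ingest per-patient dose summaries as numbers; DICOM-RT
  dose grids are not parsed, and no treatment-plan optimization or
  dose-painting plan generation is attempted.
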