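# Methods

## Radial fat-mapping

A fat-fraction slice is a 2D raster of percent fat signal per pixel in
[0, 100] with one binary mask per muscle side and a continuous center of
rotation (CoR) coordinate. ROIs are full distance shells of width 2 pixels
(in pixel units of the acquisition grid; `pixel_spacing` defaults to 1.0
unit/pixel because in-plane resolution is an acquisition property, not an
analysis one): ROI *k* holds the in-mask pixels with
r_min + 2k ≤ d < r_min + 2(k+1), where d is Euclidean distance from the CoR
and r_min the minimum in-mask distance. Binning starts at r_min rather than
at the CoR itself because the muscle never touches the CoR; anchoring at
r_min keeps shell occupancy stable across subjects. No angular sectoring is
applied — the ROIs are radial increments only.

Each ROI's mean FI% is placed at the ROI's mid-depth, computed as the mean
distance of its member pixels (not the geometric shell midpoint: the mean
respects the area weighting of the outer part of a shell and makes a linear
fat ramp reproduce exactly at interior grid nodes). Depths are normalized
per side and slice to 0–100 % of (max − min in-mask distance), then linearly
interpolated onto a fixed 101-node integer-percent grid. Endpoints do not
extrapolate: nodes outside the first/last ROI mid-depth take the nearest
ROI's value. An empty intermediate shell (a mask gap) is interpolated across
with a warning. The four curves per subject and level (left/right × two
slices) are averaged node-wise without area weighting; distance
normalization happens per side *before* averaging, so left and right
muscles of different radial extents align by relative depth.

Scalar metrics: overall FI% is the pixel-weighted mean over all in-mask
pixels of both sides and slices; deep15 FI% is the mean of curve nodes 0–15
inclusive (16 nodes — a closed window, documented so the choice is
auditable). A constant field therefore yields deep15 = overall = the
constant, and the identity ramp yields deep15 = 7.5.

Consequences of pixel discretization: a noise-free synthetic subject
reproduces a *constant* baseline exactly and a *linear* baseline exactly at
interior nodes; curved baselines reproduce to ≈0.15 FI% at interior nodes,
with larger deviations only at the clamped endpoint nodes. Tests assert
exactly these attainable tolerances.

## 1D SPM and random-field-theory inference

At each of the Q = 101 nodes the curve value is regressed by OLS on a design
with intercept, covariate of interest and adjusters (age, sex as a female
indicator, BMI). Continuous covariates are z-scored — the t-field is
invariant to any affine rescaling of a column, so this is presentation only.
The t-field is t(q) = β̂(q)/SE(β̂(q)) with ν = n − p degrees of freedom. A
numerically exact fit (zero residual) is reported as t = ±∞ rather than a
rounding-noise ratio.

Smoothness is estimated from the residual field with the standard lattice
estimator: the residuals are normalized node-wise, the mean squared gradient
λ of the normalized field is averaged over nodes, and
FWHM = √(4 ln 2 / λ), clipped to [1 grid step, field length]. Smoothing
white noise with a Gaussian kernel of FWHM w yields a field whose estimate
converges to w, which the tests verify.

The familywise-corrected threshold solves

P(max T > u) ≈ P(T_ν > u) + R₁ · ρ₁(u),  ρ₁(u) = √(4 ln 2)/(2π) · (1 + u²/ν)^(−(ν−1)/2)

for the tail level (α/2 per tail; inference is two-tailed by default with
clusters reported signed, and one-tailed mode is available). **Resel count:**
R₁ = max(L/FWHM − 1, 0) where L is the field length in grid percent. The
−1 makes the limit exact: a field as smooth as its entire length carries a
single effective t variate, and the point probability is already counted by
the first term, so at FWHM = L the threshold reduces to the pointwise t
quantile; for rough fields the count approaches the usual L/FWHM. The
solver brackets u between the pointwise quantile (a lower bound, since the
cluster term is positive) and a doubling upper bound, then uses Brent's
method to 1e-10.

Clusters are maximal runs of nodes with |t| > u* and uniform sign; endpoints
are refined by linear interpolation of the t-field to the exact crossing, so
sub-node extents are expressible. Each cluster receives the standard
extent-based RFT p-value: with expected cluster count E[m] (the expected EC
at u*), expected suprathreshold volume E[N], and extent k in resels,
P(K ≥ k) = exp(−βk²) with β = (Γ(3/2)·E[m]/E[N])², and
p = 1 − exp(−E[m]·P(K ≥ k)). Like all RFT extent approximations it is
asymptotic in smoothness and is used for reporting, not thresholding.

Cohorts below 20 subjects trigger a warning: the EC approximation degrades
at very low degrees of freedom. Subjects with missing covariates are
dropped listwise with a logged count.

## Cohort models

* Chronicity OLS: chronicity (years; collected in months but modelled in
  years) on mean deep15 *or* overall FI% (average of L4L5/L5S1), mean
  Pfirrmann grade, age, sex (male reference), BMI.
* Activity OLS: weekly MET-minutes on chronicity, pain NRS, age, sex, BMI.
* Mixed models: per-level deep15 or overall FI% (two rows per subject) on
  chronicity, level-specific Pfirrmann grade, MET-minutes, pain, age, sex,
  BMI and a lumbar-level indicator, with a per-subject random intercept.
  Estimation is REML (falling back to ML with a log entry if REML does not
  converge); continuous fixed effects are z-scored by default (switchable)
  so coefficients are comparable across predictors whose native scales
  differ by orders of magnitude. p-values and confidence intervals for the
  mixed fixed effects use the Wald normal approximation; at the default
  cohort size (223 subjects × 2 levels) the difference from
  degrees-of-freedom-adjusted intervals is negligible, and the coverage
  simulations in the test suite confirm nominal 95 % coverage. OLS models
  use exact t intervals.

Degenerate inputs raise: constant predictors, zero-variance outcomes, and
rank-deficient SPM designs (reported with the offending columns).

## Synthetic cohort generator

The generator emulates a chronic low-back-pain imaging cohort so that every
downstream stage can be validated against known truth. Defaults describe a
223-subject cohort (53.8 % female): age 53.0 ± 15.4 yr, BMI 26.1 ± 4.4
kg/m², pain 4.45 ± 1.9 NRS, chronicity 11.9 ± 12.7 yr, activity
3164.8 ± 2920.4 MET-min/wk, Pfirrmann grade probabilities
(0.03, 0.15, 0.37, 0.32, 0.13) concentrated at grades 3–4 as typical for
degenerated lower lumbar discs in a middle-aged symptomatic cohort.
Chronicity (left-truncated at 0.25 yr, the three-months-of-pain inclusion
floor) and MET-minutes (truncated at 0) are truncated normals whose
*location* is solved by Brent's method so the truncated mean equals the
target mean — naive truncation would inflate mean chronicity from 11.9 to
≈16 yr. Pain is clipped to the 0–10 scale (a < 0.01 NRS mean shift).
Covariates are drawn independently; an optional correlation structure was
considered and rejected because no quantitative correlation target exists.

Muscle geometry is a pair of mirror-image half-annulus sectors posterior to
the CoR (inner radius 10 px, outer 34 px, 55° angular span per side with an
8° midline gap on a 96×96 raster) — deep-to-superficial geometry without
anatomical modelling. The baseline radial profile is a smooth curve in the
10–35 FI% range, fattier deep and superficial than at mid-depth. Injected
effects add sign × slope × z(covariate) FI% to pixels whose normalized depth
falls in a stated window; covariates are z-scored cohort-wide first so
slopes are per SD. Optional per-subject constant offsets (`subject_sd`)
supply between-subject variance for mixed-model validation; pixel noise is
i.i.d. Gaussian, clipped with the signal to [0, 100].

For desk-scale simulation studies a curve-level generator skips rendering
and injects smooth Gaussian noise directly at the curve nodes: white noise
circularly convolved with a Gaussian kernel of FWHM 10 grid-percent
(yielding a field of exactly that random-field smoothness, rescaled to
pointwise sd 4 FI% by the exact sum-of-squared-kernel-weights factor).
These are the conditions for the error-rate and spatial-recovery
experiments: FWER calibration uses 500 null cohorts of n = 100; spatial
recovery uses 50 cohorts of n = 223 with a 1.5 FI%/SD chronicity effect in
the deepest 24 %; the permutation cross-check uses 10 cohorts × 1000
permutations; model coverage uses 200 replicates of n = 223.

What the generator does **not** emulate: anatomically realistic muscle
shapes or 3D volumes, segmentation error or rater disagreement, epimuscular
fat (masks exclude it by construction), spatially correlated *pixel* noise,
non-stationary curve smoothness, and covariate correlations. Passing tests
therefore demonstrate the correctness and calibration of the computational
pipeline under its stated assumptions — not that real multifidus data meet
those assumptions.

## Determinism

All randomness flows from integer seeds through `numpy.random.SeedSequence`;
the pipeline fans one global seed into per-stage child seeds, so regenerated
cohorts are bit-identical and a repeated run reproduces the artifact hash
manifest exactly.

## Known limitations

* RFT assumes a stationary, reasonably smooth Gaussian residual field; the
  global FWHM estimate can be dominated by a very smooth variance component
  (e.g. subject-constant offsets), which lowers the threshold toward the
  pointwise quantile. Under such mixed noise the permutation oracle in the
  test suite is the more faithful reference.
* Cluster p-values use the Gaussian-field extent approximation at t-field
  thresholds; they are approximate for small ν.
* The CoR is an input; the package does not estimate it from vertebral
  anatomy, and no lordosis/obliquity correction is applied.
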