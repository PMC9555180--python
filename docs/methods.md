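# Methods

`rangefc` implements a distance-resolved voxelwise functional-connectivity
(FC) analysis for resting-state fMRI, together with the synthetic cohort
machinery needed to exercise and validate it end to end without access to
clinical scan data. This note records the models, the defaults and why
they were chosen, the numerical decisions, and the known limits of what
the synthetic validation demonstrates.

## The core statistic: short- and long-range FC strength

For every voxel *i* inside the analysis mask, the Pearson correlation
r<sub>ij</sub> of its time series with every other in-mask voxel *j* is
Fisher-transformed, z = ½·ln((1+r)/(1−r)), and the z values are summed —
the *FC strength* (also called functional connectivity density) of the
voxel. The sum is split by the Euclidean distance between voxel centers
in template (MNI-style) mm coordinates,

D<sub>ij</sub> = √((x<sub>i</sub>−x<sub>j</sub>)² + (y<sub>i</sub>−y<sub>j</sub>)² + (z<sub>i</sub>−z<sub>j</sub>)²),

into a short-range part (D < 75 mm) and a long-range part (D ≥ 75 mm),
and by sign into positive and negative components, yielding four maps per
subject: spFC, lpFC, snFC, lnFC. Numerical decisions:

* **Boundary rule.** "Below 75 mm" vs "over 75 mm" leaves D = 75 exactly
  unassigned; we assign it to the long-range part so the split is an exact
  partition (spFC + snFC + lpFC + lnFC equals total strength, and
  spFC + lpFC equals total positive strength, to machine precision).
* **|r| = 1.** Degenerate correlations (duplicated series) are clamped to
  1 − 10⁻⁷ before the transform so maps stay finite.
* **Zero-variance voxels** receive all-zero maps and a warning; they
  contribute nothing to other voxels.
* **Blocking.** The V×V correlation matrix is never materialised; rows are
  processed in blocks (default 512 voxels) with distances generated on
  demand. The result is block-size independent and is verified against a
  brute-force all-pairs oracle to 10⁻¹⁰ relative error in the tests.
* Euclidean distance is an acknowledged approximation to axonal path
  length; no geodesic correction and no minimum-distance exclusion of
  smoothing-contaminated neighbours is applied.
* Group analysis uses the positive maps only (spFC, lpFC); the negative
  maps are computed and stored because the partition invariant is the
  cheapest strong correctness check, but negative correlations are
  interpretively ambiguous and test–retest unstable.

## Preprocessing residue

The pipeline assumes data already realigned, normalised and smoothed.
What remains before FC computation:

* **Framewise displacement** (Power form): FD<sub>t</sub> =
  Σ|Δtranslation| + R·Σ|Δrotation| with sphere radius R = 50 mm,
  FD₁ = 0. Exclusion when any translation exceeds 2 mm or any rotation
  exceeds 2° (rotations held in radians internally).
* **`clean_series`**: linear detrend, confound regression and 0.01–0.08 Hz
  band-pass, implemented as a *single* least-squares projection onto
  {intercept, trend, confounds, out-of-band DFT sine/cosine pairs}.
  Doing all three simultaneously avoids the classic artifact of
  sequential pipelines (filtering reintroducing regressed signal), and
  because the operation is an orthogonal projection it is exactly
  idempotent — a property the tests assert. The design must keep fewer
  columns than timepoints; with the default band and TR = 2 s this is
  satisfied for any series of ≥ 40 volumes.

## Group inference: voxelwise GLM + random-field cluster correction

Per voxel, ordinary least squares with intercept, group coded +1
(patient) / −1 (control), and mean-centered covariates (age, sex 0/1,
education, mean FD, depression and anxiety scores). With no covariates
the group t is exactly the pooled two-sample t.

Cluster-level multiple-comparison control follows stationary Gaussian
random-field theory:

1. **Smoothness.** Residual maps are standardized voxelwise; for each
   axis the variance λ<sub>d</sub> of first differences between in-mask
   neighbours (pooled over subjects) gives
   FWHM<sub>d</sub> = voxel<sub>d</sub>·√(4 ln 2 / λ<sub>d</sub>), and the
   resel count R₃ = V·voxel volume / ∏FWHM. Note the discrete white-noise
   limit of this estimator is √(2 ln 2) ≈ 1.18 voxels, not 1.0; the
   estimator is accurate (±5%) once smoothness reaches ~3 voxels, the
   regime the correction needs anyway.
2. **Thresholding.** The t map is Gaussianized (t→z through matched tail
   probabilities, capped at |z| = 38 where the t survival function
   underflows) and thresholded at u = Φ⁻¹(1 − voxel p), default
   voxel p = 0.001. Suprathreshold voxels are grouped with
   26-connectivity (configurable 6/18/26).
3. **Cluster p.** With E[m] = R₃·ρ₃(u) the expected cluster count from
   the 3D Euler-characteristic density and E[N] = R₃·Φ̄(u) the expected
   suprathreshold resel volume, a cluster of k resels has
   P(max extent ≥ k) = 1 − exp(−E[m]·exp(−β·k^{2/3})) with
   β = (Γ(5/2)·E[m]/E[N])^{2/3}. Lower-dimensional resel terms are
   omitted (negligible at u ≈ 3.1).
4. **Two-sidedness.** Positive and negative tails are processed
   separately at the voxel threshold, and the cluster-level α is
   Bonferroni-split across the tails (each one-tailed cluster p is
   doubled). This keeps the overall family-wise rate at the nominal
   cluster p; without the split a two-tailed analysis would target twice
   the nominal level.

Calibration is verified by simulation rather than by formula trust: on
500 smooth Gaussian null cohorts (8000 voxels, FWHM 3 voxels, n = 20/20)
the measured family-wise rate of ≥ 1 surviving cluster is ~0.01–0.05,
i.e. at or below the nominal 0.05. The correction is mildly conservative
in this regime (tail Bonferroni plus the high-threshold approximation);
we prefer that bias direction for a screening analysis.

## Clinical statistics

Pooled-variance (Student) two-sample t tests for continuous demographics
— the pooled form is used deliberately because it reproduces published
summary-statistics tables computed the same way, and it is exactly
recomputable from (mean, SD, n) triplets; Welch's correction is not, and
gives visibly different t values when group variances differ by an order
of magnitude (e.g. symptom scores in a patient/control design). Pearson
χ² without continuity correction for 2×2 sex tables, for the same
reason. FC–clinical association uses plain Pearson correlation in
patients only, Bonferroni-corrected over the (cluster × variable) pairs
actually tested; constant columns are reported as undefined and excluded
from the test count.

## SVM classification

Features are per-cluster means of the subject maps (a voxel-vector mode
exists). Labels: +1 patient, −1 control. Each leave-one-out fold scales
features to [−1, +1] by training-fold min/max; held-out values pass
through unclipped. The RBF-kernel classifier's (C, γ) come from a
powers-of-two grid (C ∈ 2^{−5..15}, γ ∈ 2^{−15..3}, step 2²), ties broken
toward the smallest C then the smallest γ.

Two selection designs are exposed. *Nested* (default): (C, γ) re-selected
inside each fold by inner stratified 5-fold CV — the leak-free accuracy
estimate. *Global*: one grid search by leave-one-out over the whole
sample, then fixed parameters per fold — mirroring the common clinical
literature design, which lets the test subject influence selection and is
therefore optimistically biased; it is provided for comparability, and
the bias is the user's to own.

Significance uses a label-permutation test repeating the full procedure
per permutation, p = (1 + #{perm ≥ observed}) / (1 + n_perm), never zero.
One behaviour worth knowing: under a *single* balanced permutation,
leave-one-out accuracy is systematically **below** chance (removing the
held-out subject biases the training majority against its class — the
well-documented below-chance artifact of CV on null data), and the nested
variant, which tends to pick maximally regularised models on null data,
can reach accuracy 0. Chance level should therefore be judged from the
permutation *distribution*, not one permuted run; the permutation test
itself is unaffected (the observed statistic is compared against that
distribution).

Confound-only baselines (age, mean FD, sex, education) run the identical
protocol on one nuisance column each.

## The synthetic cohort

The generator's defaults are the study conditions: 40 patients / 38
controls, 240 volumes at TR 2 s, an ellipsoidal mask of ≈ 3200 voxels on
an 18×22×18 grid of 6 mm voxels (mm origin at the grid center, so both
sub-75 mm and supra-75 mm pairs exist), AR(1) temporal autocorrelation
0.3, Gaussian spatial smoothing FWHM 8 mm. Clinical variables are drawn
per group from zero-truncated normals with the means/SDs of a typical
medication-free OCD sample (e.g. Y-BOCS total 24.90 ± 5.73 in patients
vs 1.13 ± 0.88 in controls); sex is binomial at 27/40 vs 25/38 male.
Motion traces are Gaussian random walks whose step size targets mean FD
≈ 0.04 mm (patients) / 0.03 mm (controls) with lognormal between-subject
spread; an optional fraction of subjects receives a 3 mm jump to exercise
the exclusion rule (default 0, so the default cohort retains 40/38).

**Signal model.** Each effect region owns a unit-variance AR(1) latent
factor; member voxels load on it (baseline loading λ₀ = 1.0, i.e.
within-region r = λ₀²/(1+λ₀²) = 0.5 at baseline), voxelwise AR(1) noise
is added, and each volume is smoothed. A latent-factor construction was
chosen over an explicit V×V covariance (no V² storage, and "coupling" is
a single interpretable loading). Patients' loadings are shifted by the
region's coupling delta; for distal regions the delta applies to **both**
ends of the pair, because the cross-correlation
λ_Aλ_B/√((1+λ_A²)(1+λ_B²)) saturates in a single loading — a one-sided
shift cannot produce a usefully large long-range change. A side effect
worth noting: a positive distal delta also raises within-end short-range
coupling, so distal effects appear (genuinely) in both lpFC and spFC.

**Effect sizing.** The planted deltas are detectability choices, not
effect-size estimates — no correlation-unit effect sizes are available
to emulate. Between-subject variance of FC-strength maps is dominated by
spatially correlated correlation-sampling noise (smoothing makes
neighbouring z errors move together, so the ~600-term short-range sums do
not average it away), which a power analysis put at SD ≈ 19 strength
units at T = 240. Defaults — sphere radius 12 mm (~33 voxels), λ₀ = 1.0,
deltas −0.7 (local "sensorimotor" analogue) and +0.7 (two distal pairs) —
give planted voxel |t| ≈ 10–20 at n = 40/38, so full recovery is robust
to the cohort seed rather than marginal. Region centers sit on the 6 mm
grid, inside the ellipsoid, with distal pair separations of 90–91 mm and
all planted spheres pairwise disjoint.

Per-subject seeds are cohort seed + subject index; the clinical/motion
stream is offset by a large constant. The whole cohort is bit-reproducible
from the cohort seed.

**What the synthetic validation does and does not show.** Passing tests
demonstrate that the statistic is computed exactly as specified, that the
cluster correction controls family-wise error on smooth stationary
Gaussian nulls, and that effects of the planted kind and size are
recovered with the right sign and location. Real BOLD violates the
emulation in known ways — non-stationary smoothness, physiological and
scanner artifacts, heavy-tailed spatial autocorrelation (the regime where
RFT cluster inference is known to become anticonservative), anatomically
structured signal, and FC–symptom relationships that are not independent
draws. Published cluster tables and classification accuracies from real
cohorts are therefore *not* reproduction targets of this package; the
reproducible quantities are the ones computable from printed inputs
(summary-statistic tests, worked strength sums, ratio arithmetic) plus
the calibration and recovery properties above.

## Problem sizes used in the shipped checks

Chosen so the full suite and the acceptance script each run in minutes on
one CPU: null FWER at 500 replicates of V = 8000 (tests; 200 in the
script), the default cohort at its full 78 × 240 × ~3200 size, the
brute-force oracle on ~200 voxels × 60 timepoints, SVM permutation tests
at 99–199 permutations on a reduced powers-of-two grid (5×5 or smaller;
the full 11×10 grid is the library default). Pipeline-level null
calibration runs at 6 reduced cohorts (n = 10/10, ~800 voxels).
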