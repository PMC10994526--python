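# Methods

This note records the model, the numerical conventions, and the design
choices behind `eigenbrains`, in the spirit of a package's statistical
documentation: what is computed, under which assumptions, and what the
synthetic validation does and does not establish.

## Preprocessing

**Reference normalization.** FDG-PET intensities carry a multiplicative
per-subject global-uptake factor (dose, scanner gain, overall
metabolism). Dividing all voxels by the mean over a reference region
assumed spared by disease (the pons) removes it exactly:
`normalize(c·x) = normalize(x)` for any `c > 0`. The reference mean of
the output is 1 by construction; a non-positive reference mean is a hard
error naming the subject.

**Smoothing.** Isotropic Gaussian, parameterized by FWHM in mm
(σ = FWHM / (2√(2 ln 2)) voxels; 6 mm FWHM at 6 mm voxels → σ = 0.4247
voxels), applied to the full volume with reflective boundaries so total
mass is conserved, before masking. The pipeline order is
normalize → smooth; both commute with global scaling, so the order only
matters near volume edges, and `preprocess(..., smooth_first=True)`
swaps it.

**Voxel order.** Masked vectors are laid out lexicographically with the
x-axis fastest (Fortran ravel of the `[x, y, z]` array). The convention
is fixed so scores are bit-reproducible.

## Decomposition

**Robust scaling.** Each image vector is median-centred and divided by
its interquartile range; quantiles use linear interpolation between
order statistics (numpy's default). A flat image is an error. Rows of
the participant-by-voxel matrix are ordered by subject id regardless of
input order.

**SVD and sign convention.** Thin SVD of the scaled matrix; eigenbrains
are the right singular vectors, subject scores are `U S`. The sign of
each component is mathematically arbitrary; we flip so the
maximum-|loading| voxel is positive and record the flips. Covariance
share is the squared-singular-value share (`pct_covariance`); the
absolute-value share is also computed (`pct_covariance_abs`) since
"percentage of absolute variance" admits both readings, with the
squared share as the default output.

**No column centring by default.** Only per-image centring/scaling is
part of the model; removing the voxel-wise mean across subjects is
exposed as `column_center=True`. A consequence worth knowing: without
column centring, score columns are orthogonal in inner product but their
*Pearson* correlations are not exactly zero; with column centring both
hold exactly.

**Horn's parallel analysis.** Null replicates permute each row's entries
independently (preserving each subject's intensity distribution,
destroying spatial covariance); 100 replicates and the 95th percentile
by default; retention stops at the first component whose observed
squared singular value fails to beat its null percentile
(contiguous-prefix rule). Squared singular values are computed from the
smaller Gram matrix (`X Xᵀ` when subjects < voxels), which is exact and
roughly an order of magnitude faster than a full SVD per replicate. Two
caveats: the permutation null assumes within-subject exchangeability of
voxel values, which heavy spatial smoothing of pure noise violates
(parallel analysis is then anti-conservative); and at 95%/100 replicates
the threshold estimate itself has Monte-Carlo error — raise `n_null` for
publication-grade retention decisions.

**Projection and alignment.** New subjects are robust-scaled and
projected onto the eigenbrains; training images reproduce their stored
score rows to numerical precision. `align_components` matches estimated
components to reference patterns one-to-one by maximal |Pearson r|
(Hungarian assignment — the exact optimum of the greedy criterion) and
reports signed correlations and required flips.

## Group contrast maps

Two conventions are shipped because the verbal description "group mean
images scaled by their respective standard deviation" is ambiguous:

* `ratio` (default, the literal reading): `Z = m_a/s_a − m_b/s_b`;
* `standardized_difference`: `Z = (m_a − m_b)/s_b`.

SDs use n−1. `ratio` is antisymmetric under group exchange and invariant
to per-group rescaling; `standardized_difference` is antisymmetric only
when the two groups have equal voxel SDs. Voxels with group SD below
1e−8 are zeroed and counted rather than raised, since synthetic masks
can contain constant voxels. Controls are matched to a patient group on
size, age and sex by greedy nearest-age matching without replacement
within sex strata, ties broken by the smaller subject id
(deterministic).

## Phenotype statistics

One model per outcome, raw p-values, no multiple-comparison correction —
the convention of exploratory brain–behaviour tables; interpret
accordingly. Predictors (and continuous outcomes) are z-scored inside
the link models, so linear coefficients are standardized β and logistic
coefficients are odds ratios per SD of score. Tukey post hocs run only
when the omnibus ANOVA is significant. Levene tests use median centring
(Brown–Forsythe) by default for robustness. Chi-squared tests are
Pearson without continuity correction, with a low-expected-count flag.
Logistic fits report non-convergence and suspected separation as an
explicit status instead of silently returning diverged numbers.

CSF banding follows fixed cut-offs (p-tau 54/58 pg/ml; ATI 0.8/1.2) with
strict inequalities, as do PET positivity thresholds (PiB SUVR > 1.42,
AV1451 SUVR > 1.29). When the two CSF bands disagree the combined call
is "borderline" with both sub-bands reported — the combination rule is
this package's convention, since no standard rule exists for the
discordant case.

## LDA

The classifier is Gaussian LDA with class means, a pooled within-class
covariance (n − C denominator), priors defaulting to class proportions,
and discriminant axes from the generalized eigenproblem of between- vs
within-class scatter (at most C − 1 axes; three for four diagnostic
groups). Reported accuracy is resubstitution, the honest default when no
validation scheme is specified; stratified k-fold is available and
labelled as an extension. Two robustness variants:

* **signed log**: `sign(x)·ln(1+|x|)` — scores can be negative, so a
  plain log is undefined; the signed log is odd, monotone and fixes 0;
* **robust**: per-class minimum-covariance-determinant location/scatter
  (support fraction 0.75), pooled by class size. MCD requires more
  subjects than features per class and errors loudly otherwise — with 9
  features a 7-member class cannot be robustly estimated, and the
  package says so rather than guessing.

**Analytic age-only oracle.** For a single feature the equal-variance
LDA rule is a set of linear discriminants in `x`; the decision regions
are resolved exactly from pairwise line intersections, and expected
accuracy integrates each class's own normal (its observed mean and SD,
not the pooled one) over its region. A Monte-Carlo oracle cross-checks
the closed form. Note the model mismatch is deliberate: the *rule*
assumes a shared variance, the *evaluation* uses the per-class SDs.

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes: four
patient groups of 52/30/7/28 plus 117 matched controls on an
18×22×18 grid of 6 mm voxels (5120-voxel brain mask; 3×3×3 reference
block). Each image is

```
g_i · ( baseline + Σ_k loading_ik · pattern_k + noise ),
```

with `g_i ~ U(0.7, 1.4)` a global-uptake nuisance removed by reference
normalization, `noise` iid Gaussian with SD 0.06 (≈6% voxel CV of the
unit baseline — realistic for smoothed, pons-normalized FDG-PET), and
patterns built by smoothing seeded white noise (14 mm FWHM), zeroing the
reference region (the "pons" is spared by construction — which is
exactly why it anchors normalization), mean-centring, and Gram–Schmidt
orthonormalization. The baseline is spatially constant: a structured
shared profile would survive per-row median centring and masquerade as
an extra common component.

**Loading design.** Group means follow the qualitative ordering of the
real phenotypes (component 1 highest for bvAD, component 2 for dAD,
component 3 higher for dAD/aAD than bvFTD; controls 0). Their magnitudes
were solved once so that the size-weighted covariance of the *effective*
loadings — after per-image IQR scaling, which shrinks rows in proportion
to their signal content — is diagonal with separated variances
(≈4.1/2.6/1.5). This matters: if the population loading covariance is
not diagonal in the planted basis, the population principal axes are
rotations of the planted patterns and "pattern recovery" would be
ill-posed as a test of the decomposition rather than of the simulation.

**Moment conditioning.** Sampled loading deviations are recentred and
sample-whitened per group, so each group's sample mean and covariance
equal the configured values exactly in every realization. Without this,
sampling noise of the loading moments (standard deviation of a
covariance off-diagonal ≈ √((λ_j+λ_k)/n) ≈ 0.13 at these settings)
rotates the leading eigenvectors within the planted subspace by several
degrees on unlucky seeds, independently of image noise. Conditioning is
a standard simulation variance-reduction device; the cost is that
loading marginals are no longer exactly Gaussian and cohort-to-cohort
moment variability is suppressed — acceptable for a testbed whose job is
to present the analysis with exactly its assumed structure.

**Clinical table.** Ages are drawn per group from the published
means/SDs (onset, with scan = onset + a positive duration); controls
sample the patient mixture for age and sex, making them matched by
construction. Cognitive composites are linear functions of the loadings
plus Gaussian noise, mapped to the scaled-score convention (population
mean 10, SD 3, calibrated on the control distribution). Behavioural
flags are Bernoulli through a logistic link; controls are symptom-free.
Biomarkers jitter around published per-group medians; the link
coefficients are free parameters of the simulation (no generative values
exist in the literature — published coefficients are estimates on real
data) and are exposed in `SimConfig`.

`make_reference_cohort` is separate from the stochastic generator: a fixed
117-row categorical table reproducing the published per-group symptom,
sex and APOE4 counts exactly, for tests that need printed cells rather
than random draws.

**What passing tests show — and don't.** On this generator, Horn's
method recovers the planted rank in 20/20 seeded cohorts and the
estimated eigenbrains align with the planted patterns at |r| ≥ 0.95,
degrading monotonically with noise. Real FDG-PET differs in ways the
generator deliberately omits: spatially correlated, non-Gaussian noise;
partial-volume and scanner PSF effects; registration error; baseline
anatomy shared across subjects; diagnostic groups that overlap far more
than the planted ones (the synthetic LDA reaches ~100% where the
corresponding real-data analyses sit near 80%). Passing tests establish
the *software* computes the intended quantities and that the method
works when its assumptions hold — not that real cohorts will yield
patterns this clean.

## Problem sizes and determinism

Validation suites use 117 + 117-subject cohorts on the 5120-voxel mask
with 100-replicate parallel analysis — sizes chosen so the decomposition
is overdetermined yet the full 20-seed recovery suite runs in about a
minute. Every stochastic step takes an explicit integer seed; cohorts
are generated from one seed sequence with per-subject child streams, so
all outputs are bit-reproducible. Scripts and library functions never
share hidden RNG state.

## Interfaces

The package is organised as scikit-learn-style estimators
(`EigenbrainDecomposition`, `EigenvalueLDA`) with module-level functions
as thin wrappers, so the pieces compose with sklearn model selection.
Images and masks travel as NIfTI, tables as CSV, configurations and
reports as JSON. The library API (plus `scripts/acceptance.py`) is the
intended interface; no console entry points are installed.
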