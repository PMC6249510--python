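# Methods

This note documents the statistical procedures implemented in `oppomark`,
the synthetic study the test-suite runs them on, and the design decisions
taken where the problem left genuine freedom.

## Data model

A study is a set of cohorts, each a `BetaMatrix` (samples × CpG probes,
beta values in [0, 1], NaN mask for missing measurements, optional
per-measurement detection p-values) plus a `SampleSheet` (subject pairing,
cohort, timepoint/group, age, sex, race with six categories, batch,
optional VO₂-increase flag, and — in the drinkers-only cohort — the 13
behavior scores: five ADS subscales, four AUDIT items/total, four ICS
scales). Beta matrices are exchanged as wide delimited text (probes as
rows); values outside [0, 1] are errors, never clipped silently. All
thresholds live in one validated `RunConfig`:

| parameter | default | meaning |
|---|---|---|
| `detect_p_max` | 0.05 | detection p strictly above → measurement set missing |
| `max_missing_rate` | 0.05 | samples/probes with missing fraction strictly above → dropped |
| `sd_threshold` | 0.06 | inter-subject SD a probe must strictly exceed to be retained |
| `age_screen_p` | 0.01 | uncorrected p below which a probe counts as age-driven |
| `family_alpha` | 0.05 | family-wise level of Bonferroni-controlled discovery |
| `step2_alpha` | 0.05 | uncorrected level of the behavioral verification step |
| `pca_variance_target` | 0.90 | cumulative variance the behavior PCs must reach |
| `z_contrib_threshold` | 1.5 | \|z\| cut for component contributors |

## Quality control

The stage order is fixed: detection-p masking → sample missing-rate filter
→ probe missing-rate filter and cross-hybridizing-probe exclusion →
per-probe batch adjustment → SD filter → (longitudinal cohort only) age
screening. SDs are therefore computed on analysis-ready, batch-adjusted
data; batch adjustment precedes the SD filter by design and is
configurable by calling the stages directly.

* **Batch adjustment** regresses batch dummies out of each probe on
  complete cases and returns residual + probe mean; output is clipped to
  [0, 1] with the clip count logged. On data where a group contrast is
  balanced across batches the group coefficient is unchanged (orthogonal
  projection), which the tests assert.
* **Replicate error.** Technical replicate pairs re-measure the same
  samples; the per-measurement error SD is the SD of paired differences
  divided by √2, pooled over probes and pairs — the standard
  technical-replicate estimator. The pipeline pools per-cohort estimates by
  maximum (more stringent filtering, one threshold for all cohorts).
* **Age screening** fits beta ~ age + sex + race dummies per probe and
  flags probes with age-coefficient p below 0.01 (uncorrected — a
  deliberately liberal exclusion). Only one sample per subject (the
  baseline) enters, since duplicated subjects share biology and would
  inflate the association (~8% exclusions at a nominal 1% when both
  timepoints are used). The exclusion set is the union of this screen with
  an a-priori age-predictor probe list supplied as a file.
* **Cell-type deconvolution** solves, per sample, min‖Pᵀw − x‖² over the
  probability simplex by projected gradient with the 1/L step (monotone
  residual decrease; sort-based Euclidean simplex projection). Reference
  profiles are an input; at least 20 probes must overlap, and
  near-identical profiles raise a non-identifiability error.
* Per-probe regressions throughout use complete cases, grouping probes by
  missingness pattern for one batched solve per pattern. A design column
  that becomes constant under a pattern (a rare race level absent from the
  complete cases) is dropped for those probes only; genuine collinearity
  raises an error naming the aliased column. Race is dummy-coded with the
  most frequent level in the analyzed set as reference.

## Association engines

* **Exercise (paired).** Per probe, paired t-test of follow-up minus
  baseline on complete pairs (≥3 required; fewer → probe skipped and
  logged). Zero-variance differences are degenerate: p := 0 when the mean
  difference is non-zero, p := 1 otherwise. Significance is Bonferroni at
  `family_alpha` over the probes actually tested — discovery counts are
  data-dependent outputs, never constants.
* **Drinking (two-step).** Step 1: per-probe OLS of beta on drinker/control
  with race dummies; Bonferroni as above; group means reported unadjusted.
  Step 2: the 13 behavior scores are standardized and decomposed by PCA on
  the correlation matrix (the instruments have heterogeneous ranges, so
  unstandardized PCA would let one scale dominate); k is the smallest
  number of PCs reaching the variance target. Each step-1 hit is regressed
  on each PC separately (adjusting age, sex, race); a probe is verified
  when its minimum PC p-value is below `step2_alpha`, uncorrected — the
  most inclusive reading of "associates with at least one behavioral
  dimension"; `all` and single-PC modes are exposed. The final set is
  monotone in the step-1 output. All tests are two-sided on the beta scale.

## Marker calling and confirmations

Hits of the two analyses are intersected; directions come from the signs
of the test statistics (drinker-vs-control coefficient; follow-up-minus-
baseline mean). When a coefficient sign disagrees with the raw
mean-difference sign (confounding), the coefficient wins and the row is
flagged. A marker is *opposite* iff hypo-in-drinkers ∧ hyper-after-exercise
or the reverse; exact ties classify as "none" and can never be opposite.
Post-hoc confirmations re-test the opposite markers (i) in regressions with
cell-type proportions as covariates (dropping the last proportion column to
break the simplex collinearity; for the longitudinal cohort the paired test
becomes a timepoint-factor regression), and (ii) in subsamples — the
participants whose VO₂ max increased, and a race-matched case-control
subset built by greedy exact matching on race with nearest-age pairing —
reporting per-marker direction consistency against the primary calls.

## Multivariate fusion

The opposite markers (covariate-residualized per probe) and the
standardized 13-score matrix are each decomposed as X = A·S by Infomax ICA:
PCA-whitening of the feature covariance to exactly k dimensions, then
natural-gradient ascent with the logistic nonlinearity,
W ← W + η(I + (1 − 2y)uᵀ/n)W, fixed step η = 0.1 halved on blow-up and
annealed ×0.8 every 500 iterations (a fixed natural-gradient step can
orbit the optimum; annealing converts the orbit into convergence),
tolerance 1e−7, 10,000 iterations. The *samples* are the statistical
observations, so the loading columns of A are the maximally independent,
non-Gaussian sequences over participants and S carries each feature's
component score; each component's sign is fixed so its largest-|score|
feature is positive. This orientation matters: whitening over the 13–15
features instead would leave ~14 observations to estimate the unmixing
matrix at n = 281, making the decomposition practically unidentifiable.

**Component number** is chosen by a resampling stability criterion
(ICASSO-style stand-in for the literature's stability selection, which is
defined only by citation): for each candidate k, the model is refit under
random restarts *and* bootstrap resampling of the samples; pooled
components (loading sequences evaluated on the original samples) are
clustered by absolute correlation, each cluster scored as mean
within-cluster |r| minus mean between-cluster |r|, and the chosen order is
the **largest candidate whose worst cluster stays ≥ 0.5**. Maximizing the
mean index instead would degenerately prefer k = 1, since under-fitting is
always reproducible; requiring every component to be stable before
crediting a larger order recovers planted model orders while pure Gaussian
noise leaves all candidates unstable and falls back to the smallest
candidate with a warning. At least 5 restarts are required (10 default).

**Cross-modality association**: Pearson correlation of every pair of
loading columns, exact t-transform p-values (n − 2 df), Bonferroni over
all k₁·k₂ pairs (2 × 7 components → 14 pairs at 0.05/14). For each
significant pair the contributors are the features whose standardized
source scores exceed |z| > 1.5, reported with signs.

## The synthetic study

The generator's defaults are the study conditions the tests run under:
53 exercise subjects (baseline + follow-up; 29 flagged VO₂-increased),
81 + 81 age/sex-matched drinkers and controls, 281 drinkers with complete
behavior vectors, 2,000 probes (a desk-scale stand-in for a 27K array),
10 technical replicate pairs per cohort.

* **Signal.** Planted classes partition the probes: 40 exercise-only, 40
  drinking-only, 8 overlapping-concordant, 15 overlapping-opposite (9
  hypo-in-drinkers / 6 hyper, mirroring the worked example's split), 30
  age-driven (slope 0.004 beta/yr), 30 batch-driven (offset 0.05), rest
  null. Planted |Δβ| = 0.08, above the 0.06 retention threshold.
* **Noise.** Each sample's baseline profile is a convex combination of
  reference cell-type profiles (Dirichlet(8, 2) proportions over a
  buccal-like and leukocyte-like type; 10% of probes discriminate the
  types by 0.25 beta), plus a subject-level biological effect (SD 0.04 at
  "variable" probes — 60% of nulls and all planted probes — 0.02
  elsewhere), plus Gaussian measurement noise on the beta scale (SD 0.045
  exercise, 0.06 drinking cohorts, matching the replicate-error framing),
  clipped to [0, 1] with the clipping rate logged (< 10% by contract).
  These SDs were set analytically so that variable probes clear the SD
  filter while the planted shift retains high power at the given sample
  sizes; planted probes get mid-range (0.32–0.68) baseline betas, as
  genuinely variable CpGs must, which also keeps their effects away from
  the clipping bounds.
* **Behavior.** Three instrument-wise latent factors (inter-factor
  correlation 0.5, loadings 0.8, Laplace-distributed — severity scales are
  heavy-tailed, and non-Gaussian latents are what make the ICA
  decomposition identifiable) generate the 13 scores with fixed per-measure
  scales/offsets; drinking-affected probes covary with the standardized
  mean factor ("severity") at signed r = 0.25. In the linked fusion
  scenario an extra Laplace latent ties two opposite-class probes
  (r = 0.7 each) to the ICS total score (loading 1.0); these two probes
  carry no separate severity link, so the planted multivariate pattern is
  distinct from the diffuse severity association.
* **Confounding.** Demographics (age/sex distributions, race frequencies
  per cohort and group) mirror the study-wise table, including the race
  imbalance between drinkers and controls that the covariate adjustment
  must absorb; race-driven probe effects can be planted explicitly.
  A-priori exclusion lists (cross-hybridizing; age-predictor) are drawn
  from non-planted probes, as befits lists defined independently of the
  study.
* Identical seeds reproduce every cohort bit-for-bit; all stage seeds
  derive from one root seed by labeled derivation.

**What passing tests do and do not show.** The generator emulates the
statistical structure the pipeline assumes — additive effects on the beta
scale, Gaussian technical noise, linear age trends, a low-rank behavior
model. Real methylation data add probe-type chemistry effects,
genotype-driven outliers, correlated probe blocks and non-additive
cell-composition effects; recovery rates measured here bound what the
pipeline can do when its assumptions hold, not what it will do on a given
real cohort.

## Problem sizes in the shipped checks

The test-suite's end-to-end checks run the full pipeline at the default
conditions over 20 seeds (recovery and calibration), 100 null runs for the
loading-correlation family-wise rate, 500-observation source-separation
checks, and 20-seed fusion recovery. `scripts/acceptance.py` re-derives the
headline quantities at 5 pipeline seeds plus single runs of the remaining
checks; on one CPU the suite completes in under ten minutes and the
script in well under a minute.

## Known limitations

* The replicate-error estimator assumes exchangeable technical noise
  across probes; probe-specific error variance is not modeled.
* Deconvolution is constrained projection onto supplied reference
  profiles; it does not re-derive reference libraries and inherits their
  biases.
* The stability index is a pragmatic stand-in for the cited stability
  criterion; other clusterings (partitioning around medoids, consensus
  matrices) are reasonable and may choose different orders on borderline
  data.
* Bonferroni control is the implemented multiplicity procedure throughout;
  FDR alternatives are deliberately out of scope.
* Pathway enrichment of marker genes is not computed; a static
  enrichment table ships as a documentation fixture only.
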