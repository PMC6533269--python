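# Methods

This note documents the statistical procedures implemented in
`summedstates`, the generative model behind its synthetic data, the
defaults and numerical choices, and what the package's passing tests do and
do not establish about real data.

## The analysis

**Pattern preparation.** Each participant's voxels × conditions coefficient
matrix is z-scored within participant: every condition's voxel vector is
standardized to mean 0 and sample (n−1) sd 1 across voxels. Standardizing
across voxels removes per-condition amplitude differences so that
downstream Pearson correlations compare pattern *shape* — the standard
multivariate-pattern reading. Constant columns are hard errors, never
silently dropped. State patterns are then averaged element-wise across
participants into one group set.

**Voxel selection (optional).** Voxelwise reliability is the correlation of
a voxel's condition profile between the averages of two random half-splits
of participants, averaged over `n_splits` seeded splits (odd participant
counts split floor/ceil). Patternwise reliability at a threshold is the
between-half pattern correlation per condition, restricted to voxels at or
above the threshold, averaged over conditions and splits. The returned mask
is the grid argmax of patternwise reliability; ties break toward the lowest
threshold (retain more voxels), and the default grid starts at −1, a no-op
threshold, so the selected mask can never be less reliable than the full
set. The original selection jointly optimized voxelwise and patternwise
reliability; the grid argmax over patternwise reliability alone is this
package's declared simplification.

**Dual normalization and reconstruction.** The raw targets × states rating
matrix is sum-normalized first within state (each column divided by its
sum), then within target (each row of the result divided by its sum). Rows
of the output sum to 1; columns need not, by construction order. Each
target's pattern is reconstructed as the weight-row mixture of the group
state patterns. Weights must be non-negative; zero rows or columns are
errors with the offending label named.

**Scoring.** Within each participant, every reconstruction is correlated
with every actual target pattern. The matched (same-target) correlation
minus the mean of the T−1 unmatched correlations in that reconstruction's
row, averaged over targets within participant on the raw r scale, is the
participant's accuracy; a two-sided one-sample t-test and the one-sample
Cohen's d (mean/sd of participant values) summarize the group. Averaging
unmatched correlations as raw r follows the printed procedure of the source
analysis; a Fisher-scale variant is exposed as `fisher=True` because the
original aggregation scale is not stated.

**Similarity measures.** All five measures are emitted as the
strictly-upper-triangle vectorization of the symmetric T × T similarity
matrix, pairs (i, j), i < j, in row-major label order (SciPy's condensed
convention). Neural similarity: Pearson correlations of target pattern
columns. State similarity: Pearson correlations of targets' *raw averaged*
rating rows (the dual-normalized weights are used only for reconstruction).
Trait similarity: 13 trait scales are standardized (they have arbitrary
units, so this is correlation-matrix PCA), reduced to 3 principal
components — labeled power, valence, sociality by convention — with each
component's sign fixed so its largest-magnitude loading is positive, and
pairwise similarity is the negated Euclidean distance between component
scores. Negation (rather than max-minus) is the sign-preserving monotone
choice; downstream correlations are invariant to the affine alternative.
Text similarity: token counts are converted to within-document relative
frequencies after stopword removal (documents of unequal length are
otherwise incomparable), and similarity is the negated summed absolute
frequency difference (L1).

**Comparative statistics.** Item-level analyses treat similarity-vector
elements as units: Pearson r with its parametric two-sided p, and the
semi-partial correlation obtained by residualizing the *predictor* (never
the DV) on the competing predictor with an intercept — each account's
unique explanatory power for a common measure. The semi-partial p-value
uses df = n − 3, spending one degree of freedom on the estimated control
regression. Group-level RSA correlates a prediction with each
participant's neural similarity vector, Fisher-transforms (z = atanh r),
and applies a one-sample t-test; Cohen's d is reported on the z scale.
Dependent correlations sharing the DV are compared with Steiger's (1980)
Z̄₂\*, pooling via the back-transformed mean of the two Fisher z values;
the source analysis does not name its variant, and Z̄₂\* is the
better-calibrated choice in that family. The pooled covariance term is
clamped to |c| < 1, where the large-sample approximation can otherwise
stray at extreme correlations. Model fit uses the Gaussian OLS BIC,
n·ln(RSS/n) + k·ln(n) with k = predictors + intercept; Gaussian constants
are dropped consistently, so only within-DV differences are meaningful, and
an exact fit (RSS ≈ 0) is an error rather than −∞.

**Reliability and disattenuation.** The neural DV's reliability is the
split-half correlation of half-averaged similarity vectors, stepped up with
Spearman–Brown (2r/(1+r)) and averaged over seeded splits, clipped to
(0, 1] with a floored warning if non-positive. The share of *reliable* DV
variance a predictor explains is r²/reliability; shares above 1 occur by
sampling error and are returned with a warning, not truncated.

**Behavior.** Trials faster than 500 ms are implausible and dropped;
participants faster than that floor on more than 90% of their trials are
removed wholesale first (fractions computed before any trial removal; a
trial at exactly 500 ms survives, exactly 90% fast survives). The per-trial
predictor is sim(option A, reference) − sim(option B, reference),
standardized across retained trials inside the models. Choices are fitted
with a logistic (binomial GLM) model and reported as log-odds and
exponentiated odds per predictor SD; reaction times are log-transformed
(they are strongly right-skewed) and fitted by OLS, reported both fully
standardized and as log-RT per predictor SD. Mixed-effects fits are
replaced by fixed-effects models with a participant-cluster bootstrap for
the states-vs-traits coefficient contrast (resample participants with
replacement, refit the two-predictor model re-standardizing within the
resample, percentile 95% CI); the random-effects structure mainly affects
standard errors, which the bootstrap recovers at the cluster level.
Percentile (not BCa) intervals match the plain CI construction and are the
simplest defensible variant. The unfitted choice accuracy is the fraction
of trials whose chosen option is strictly more similar to the reference;
exactly tied trials are uninformative about either account and are excluded
from numerator and denominator, with the count reported.

## The synthetic world

The generator draws a pool of "true" mental-state patterns, mixes them into
person patterns with known weights, and emits every input the pipeline
consumes. Two calibrations make the generator the *exact inverse* of the
analysis, so that the noise-free limit reconstructs with matched r = 1 to
machine precision:

* true state patterns are exactly column-standardized after the i.i.d.
  standard-normal draw (the analysis z-scores state patterns, and a
  weighted sum of rescaled columns is not perfectly correlated with the
  same weighted sum of raw columns);
* the true weight matrix is the Sinkhorn-balanced form of a symmetric
  Dirichlet draw — alternating column/row normalization to convergence
  yields rows summing to 1 and columns summing to T/S, which is precisely a
  fixed point of the analysis's dual sum-normalization.

True person patterns are `states · weightsᵀ` plus an i.i.d. residual
pattern (sd `residual_signal_sd`) representing person-specific signal not
explained by states. Every participant observes truth plus homoscedastic
i.i.d. Gaussian noise (sd `participant_noise_sd`); spatial and temporal
autocorrelation are deliberately out of scope. Frequency ratings are
per-rater truth + Gaussian noise clipped at 0, averaged across raters.
Trait ratings are noisy linear images of *log* state frequencies
(`log(max(w, 1e-6))`, the floor avoiding −∞ while preserving order) through
a random states × 13 loading matrix; `trait_noise_sd` is the knob that
controls how much independent information traits carry, and at 0 traits are
a deterministic re-expression of the state profile — the condition under
which summed states should fully mediate traits. Token counts are
multinomial draws from probability vectors that are noisy non-negative
linear images of the weight rows; each document is drawn with common random
numbers (an identically seeded stream per target), so identical weight rows
yield identical documents. Choices follow a logistic model on the true
state-similarity difference; log reaction times are Gaussian around
log(`rt_base_ms`) with a negative slope on the *magnitude* of the
similarity difference (easier trials are faster). Because the analysis's RT
predictor is the signed difference, the synthetic comparison table's RT
rows are null by design — the generator encodes a difficulty effect, not a
signed-similarity effect. Pairwise similarity judgments (the fifth
measure) are per-rater reports of the true state similarity plus a shared
pair-level distortion (systematic folk judgment that does not average away)
plus idiosyncratic noise, averaged across raters.

One top-level seed fans out to independent named sub-streams (stage name →
CRC-keyed `SeedSequence`), so every output is a pure function of the
configuration and changing one stage's options never perturbs another's
draws.

### Defaults

Counts mirror the study conditions the analysis was designed for: 60
targets, 15 states, a 10,216-voxel mask, 29 person-study and 28 state-study
participants, 644 raters, 103 behavior participants × 50 trials, 13 named
trait scales (agency, experience, warmth, competence, trustworthiness,
dominance, openness, conscientiousness, extraversion, agreeableness,
neuroticism, intelligence, attractiveness). Noise magnitudes have no
published values and are this package's one-time calibration:

| parameter | default | rationale |
|---|---|---|
| `participant_noise_sd` | 1.0 | noise ≈ 2–3× the per-voxel signal sd, a lenient single-participant pattern reliability typical of event-related designs |
| `residual_signal_sd` | 0.2 | leaves states ≈ 70% of reliable person-pattern variance, the regime the summed-state account claims |
| `rater_noise_sd` | 0.05 | single-rater ratings are mostly noise (entries average 1/15 ≈ 0.067); hundreds of raters average to near-truth, matching the high planned reliability of the rating samples |
| `trait_noise_sd` | 1.0 | traits carry real but partly independent information |
| `choice_slope` | 3.0 | yields roughly two-thirds unfitted choice accuracy on the default similarity scale |
| `rt_base_ms` / `rt_sd_log` / `rt_sim_slope` | 1500 / 0.4 / −0.1 | ~1.5 s median triadic judgments, right-skewed, modestly faster when easy |
| `vocab_size` / `doc_length` / `text_noise_sd` | 300 / 2000 / 0.1 | short content-word biographies with discernible but noisy state signal |
| `pairwise_distortion_sd` | 0.15 | keeps the rating DV well correlated with, but not a copy of, the state prediction |
| `dirichlet_concentration` | 1.0 | uniform over the weight simplex (uninformative) |

## Problem sizes used in the test suite

Test and acceptance simulations choose sizes adequate for each property
rather than the full study scale everywhere: the null-calibration check
uses 1,000 datasets at 200 voxels / 10 states / 20 targets / 15
participants; the Steiger calibration uses 2,000 Monte-Carlo datasets of
100 pairs; parameter recovery uses 5,000 trials; the mediation check uses
20 seeds at the full default dimensions; the disattenuation-consistency
check uses 20 seeds at 2,000 voxels with 100 participants; the monotone
degradation sweep uses 300 voxels over noise sd ∈ {0, 0.5, 1, 2, 4} at
three seeds. `scripts/acceptance.py` runs the complete pipeline once at the
full default configuration.

## Numerical and design notes

* Sample (n−1) standard deviations everywhere; exact-zero variance is a
  hard error naming the offending condition/target/trait.
* Condensed-vector alignment is checked by label identity, reconstruction
  alignment by state-label name matching (order-insensitive); missing
  labels are errors, never imputed.
* The null hypothesis for reconstruction calibration is implemented as an
  *independent weight-row permutation per participant*: a single shared
  permutation leaves a structural matched-unmatched offset common to all
  participants (the group t-test then rejects far above nominal), whereas
  per-participant permutations make the participant-level differences
  i.i.d. mean-zero, the exchangeability the t-test assumes.
* CSVs are written with 17 significant digits and read with round-trip
  float parsing, so files-mode runs reproduce in-memory statistics exactly
  and repeated runs produce byte-identical reports (timestamps aside).
* Run configurations are strict: unknown keys are errors, not warnings.

## Limitations

The synthetic world validates the *machinery*, not the empirical claim.
Because participant noise is i.i.d. across voxels, averaging over thousands
of voxels and dozens of participants is far more efficient than in real
fMRI, where noise is spatially and temporally correlated; synthetic effect
sizes (t statistics, Cohen's d) are therefore much larger than any real
dataset would produce, and passing tests say nothing about real-data effect
sizes. The generator also omits rater response styles, scanner drift,
target-specific fame/valence confounds in text, and sequential dependencies
in the choice task. The trait account in the synthetic world is derived
from state frequencies by construction; real trait ratings could carry
genuinely independent structure, which is exactly what the semi-partial
machinery is for. The disattenuation estimator corrects for finite-sample
unreliability but not for systematic attenuation distortion (targets with
weaker signal have their similarities shrunk more), which caps the
estimated share below 1 whenever per-target signal variances differ and the
predictor ignores that.
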