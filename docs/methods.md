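# Methods

This note documents the statistical models implemented in `lipidiag`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
decisions a maintainer would want to know about.

## Study design being modelled

The pipeline targets a three-group fecal lipidomics screen: healthy
controls (CTRL), advanced adenoma (AA) and colorectal cancer (CRC),
profiled as a targeted peak-area table acquired in several batches with
interleaved quality-control injections, alongside the fecal
immunochemical test (FIT). FIT status is derived from fecal haemoglobin
with an inclusive threshold (positive iff Hb ≥ 20 µg/g feces; the
threshold is a configuration value).

Two QC materials play different roles: the **QC calibration** sample is a
fixed serum-like reference interleaved through every batch and used to
*fit* the drift correction; the **QC validation** sample is a pool of all
study samples and is used only to *assess* whether the correction
generalizes. Blank injections are carried through untouched and excluded
from every statistic; they exist for interface fidelity.

## Normalization model

Raw peak areas are assumed to factor multiplicatively as

    x_ij = s_ij · l_i · d_b(t_i) · ε_ij

biological signal `s`, per-injection loading factor `l`, a per-batch
drift multiplier linear in injection order `t`, and residual measurement
noise. The chain removes the nuisance terms in the order a targeted
lipidomics lab applies them:

1. **Linear-range filter.** A feature is removed iff strictly more than
   30 % of its non-missing *study* values exceed its annotated linear
   maximum. QC and blank injections do not count toward the 30 %
   (the rule protects quantification of study samples), and features
   without an annotation are exempt.
2. **Internal-standard (IS) ratio.** Each feature is divided by the IS
   that minimizes the relative standard deviation (sd/mean × 100) of the
   feature/IS ratio over all QC calibration injections pooled across
   batches; ties break lexicographically by IS id. This cancels `l_i`
   and any drift shared with the IS channel.
3. **Robust drift trend.** Remaining intra-batch drift of the
   IS-corrected response is estimated per (feature, batch) as the
   Theil–Sen line over injection order on the QC calibration points
   (median of pairwise slopes; intercept = median of `y − b·x`).
   Theil–Sen was chosen over M-estimators because it is deterministic,
   has a ~29 % breakdown point and needs no tuning constants. With fewer
   than two QC points the trend degenerates to a flat line (warning).
   A fitted trend that is non-positive anywhere in the batch's injection
   range is replaced by a flat trend at the QC median and logged.
4. **Anchoring.** Corrected values are rescaled so the per-(feature,
   batch) **mean** of QC calibration values equals exactly 1 — study
   abundances are expressed relative to the batch-averaged reference.
   The mean (not the median) is used for this anchor because the anchor
   is defined as a batch average; the choice is recorded in the model
   file (`batch_scale_stat`).
5. **Assessment.** Per-feature RSDs on the corrected QC validation
   injections, against a configurable ceiling (default 30 %, the
   conventional acceptance level for semi-quantitative lipidomics).

Missing values pass through normalization untouched; imputation is
deferred to classifier training, where it is actually required.

## Univariate statistics

Lipid abundances are strongly right-skewed and heteroscedastic, so the
group contrasts are rank-based throughout: the robust fold change
`log2(median_a / median_b)` (undefined and flagged when either median is
non-positive), the two-sided Wilcoxon–Mann–Whitney test (exact
enumeration when the combined n ≤ 20 with no ties; otherwise the normal
approximation with tie and continuity corrections), and Benjamini–
Hochberg q-values computed **within each two-group comparison across
features**, matching per-comparison reporting. Shapiro–Wilk p-values are
attached as annotation only; they gate nothing, since the tests are
non-parametric regardless. A minimum of 3 non-missing values per group
is required to emit a result.

## Latent-variable chemometrics

All latent models use NIPALS with skip-missing inner products.

* **Preprocessing.** Features: log2 (zeros offset by half the smallest
  positive value of the feature) then autoscaling to mean 0 / sd 1.
  Clinical covariates (standardized age, standardized fecal Hb) are
  standardized to **median** 0 / sd 1 — the asymmetry with the features
  is intentional and mirrors how the covariates enter the discriminant
  models.
* **PCA / Hotelling T².** Overview components; the per-sample
  T² = Σ_a t²_a / var(t_a) is compared with the F-form limit
  `A(n−1)(n+1)/(n(n−A)) · F_{1−α}(A, n−A)`. Outlier removal is a
  separate, explicit, logged step.
* **PLS-DA.** PLS2 on a dummy-coded class matrix. Q² = 1 − PRESS/SSY from
  7-fold venetian-blind cross-validation (folds assigned by sample order
  after a seeded shuffle; the seed is recorded on the model). Each
  training fold is re-centred before fitting; the autoscaling itself is
  estimated once on the full matrix, the convention of the major
  chemometrics packages for in-model Q².
* **OPLS-DA.** Binary contrasts only: one predictive component plus
  orthogonal components obtained by deflating the class-orthogonal part
  of the loading structure. Predictive and orthogonal scores are exactly
  orthogonal on complete data, and modeled R²X partitions into predictive
  + orthogonal parts that sum to the total.
* **CV-ANOVA.** `F = [(SSY − PRESS)/A] / [PRESS/(N−1−A)]` referred to
  `F(A, N−1−A)`, with A the number of fitted components (predictive +
  orthogonal); `PRESS ≥ SSY` gives p = 1. The df convention is recorded
  on the model for audit. Note a structural property of this statistic:
  under a true null most refitted models have Q² ≤ 0, so the null
  p-value distribution has a large mass at 1 — it is *super*-uniform
  (conservative), never anti-conservative. Calibration checks should
  therefore test `P(p ≤ α) ≤ α + slack`, not two-sided uniformity.
* **Variable selection.** VIP (over predictive components;
  mean VIP² = 1 by construction) > 1.0 together with
  |p(corr)| > 0.5, where p(corr) is the Pearson correlation between a
  preprocessed variable and the predictive score vector. Selected
  variables are reported VIP-descending.
* **Classification lists.** Cross-validated per-sample class predictions
  YpredPS are categorised per class column: > 0.65 belongs, < 0.35 does
  not, otherwise borderline (sub-flagged above 0.6). The classification
  percentage counts only confident calls: 100 · belongs/(belongs + not).
* **Model validity.** A binary contrast is reported as "no valid model"
  when CV-ANOVA p ≥ 0.05 or Q² ≤ 0; the criterion is stated in the output
  because different chemometrics tools leave this rejection rule implicit.

### Numerical decisions

NIPALS converges at a relative score change below 1e-10 within 1000
iterations. Autoscaled mostly-noise matrices have near-degenerate
eigenvalue bulks (adjacent singular-value ratios ≈ 0.995), where power
iteration is intrinsically slow; if the cap is reached with the change
already below 1e-3 the component is accepted with a warning — directions
within a near-degenerate eigenspace are statistically interchangeable for
overview and T² purposes. Only a change above 1e-3 raises an error naming
the component. Constant columns are scaled by 1 (warning) and get
p(corr) = 0 (flagged).

## Diagnostic evaluation

Feature sets compared: FIT alone (fecal Hb), FIT + the nine-member CE
panel (cholesterol and derivatives, CE 18:1/18:2/20:2/20:4/20:5/22:4/
22:5/22:6), and FIT + the two replicated CEs (18:2, 20:4). Inputs are
log2 normalized abundances plus raw fecal Hb. Missing entries are
completed by chained equations with predictive mean matching (k = 5
donors, 5 sweeps, single imputation — the completed matrix only feeds
the classifier); imputed values are always observed values of their
column. The cohort is split 70/30 with class stratification (unstratified
mode by flag), and a random forest (500 trees, √p feature subsampling,
minimum leaf 1 — recorded in every metrics row) reports OOB error on the
training split and accuracy/precision/recall/F1/ROC-AUC on the test
split, all in percent. The positive class is the diseased or more
advanced group (CRC against CTRL or AA; AA against CTRL; merged AA+CRC
against CTRL); orientation is configurable and logged. Because a single
70/30 split is a high-variance point estimate, the evaluation API sweeps
split seeds and summarises per-seed AUC deltas (panel − FIT) and the
fraction of seeds with improvement, rather than reporting one split.

## Synthetic-data generator

The generator is first-class, tested code. It emulates:

* exact group sizes 78/58/75 and per-group FIT positivity probabilities
  (21/78, 38/58, 65/75) via a Bernoulli branch into a two-sided
  log-normal mixture of fecal Hb around the 20 µg/g threshold;
* per-group age distributions (means 68.4/76.7/77.8, sds 14.9/10.0/10.7,
  truncated at 18) and gender mix (50/34/29 % women);
* log-normal feature abundances with per-feature biological sd(log2) = 1
  — chosen so that CE-panel-sized effects reach q < 0.05 at the study's
  sample sizes, mirroring the observed significance pattern;
* multiplicative group effects applied so the true median ratio equals
  the configured log2 fold-change exactly (defaults: the observed CE
  panel effects for AA and CRC versus CTRL);
* 127 features (the study's count) plus six spiked internal-standard
  channels (one per lipid class), whose measurement noise is shared with
  the features of their class — this is what makes minimum-RSD IS
  selection meaningful;
* three batches with a shared linear drift multiplier per batch (slope
  drawn from ±0.3 %/injection, i.e. up to roughly ±15 % across a batch),
  per-injection loading factors (sd(log2) = 0.2), serum-like QC
  calibration and pooled-fecal QC validation compositions interleaved
  every 10 injections, leading/trailing QC brackets and two blanks per
  batch;
* 2 % missingness, completely at random, in study samples only.

All randomness flows from a single seed through split substreams; the
ground-truth record (true group medians, batch drift lines, intended IS
assignment, missing mask) is bit-reproducible from (config, seed).

It does **not** emulate: nonlinear or retention-time drift, batch-specific
response factors beyond the linear trend, censoring-type (intensity-
dependent) missingness, isotope patterns or chromatographic peak shapes,
or correlation structure between lipid features beyond the shared IS
channels. Consequently, passing recovery tests demonstrates correctness
of the estimators under the stated error model, not robustness to every
artefact of real acquisitions; with independent features, latent models
on real data will show higher R²X per component than on these synthetic
matrices.

## Problem sizes used in the shipped checks

The test suite exercises the generator at the study's sample sizes
(211 study samples, 127 features, 3 batches) for single-run properties;
repeated-seed properties use 200 simulated studies for fold-change
recovery/error control and 50 train/test split seeds for the classifier
comparison; null calibration of CV-ANOVA uses 200 label permutations at
n = 60. `scripts/acceptance.py` runs one full study simulation end-to-end
plus a 10-seed split sweep. These sizes are the package's reporting
choices and are stated here so results can be reproduced exactly.

## Known limitations

* Games–Howell p-values rely on the studentized-range distribution with
  Welch degrees of freedom; for very small groups (n < 5) the
  approximation is rough, as in any implementation.
* OPLS-DA score orthogonality is exact only on complete data; with
  missing entries the skip-missing inner products make it approximate.
* CV-ANOVA significance and Q² share one cross-validation, so they are
  not independent pieces of evidence for the same model.
* The PMM imputer uses ordinary least squares as its conditional model;
  strongly nonlinear feature dependencies would call for a richer
  regression, which the diagnostic use here does not need.
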