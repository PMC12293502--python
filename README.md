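# lipidiag

Diagnostics from fecal lipidomics for colorectal-neoplasia screening.

Colorectal cancer (CRC) screening currently rests on the fecal
immunochemical test (FIT), which quantifies haemoglobin in stool and is
called positive at ≥ 20 µg Hb/g feces. FIT is insensitive for advanced
adenoma (AA), the premalignant stage where early detection matters most.
Targeted fecal lipidomics offers complementary signal: cholesteryl esters
(CEs) — cholesterol esterified to a fatty acid, e.g. CE(20:4) — are
enriched in the stool of CRC patients, and panels combining fecal Hb with
CE abundances can sharpen the three-way discrimination of healthy controls
(CTRL), AA and CRC.

`lipidiag` is a reusable, tested implementation of that analysis chain for
targeted peak tables (samples × lipid features with injection order, batch
and QC annotations), aimed at metabolomics analysts and methodologists who
want to run, audit or stress-test the workflow:

* **cohort** — metadata validation, FIT status derivation, per-group
  descriptive statistics; one-way ANOVA + Brown–Forsythe Levene +
  Games–Howell post hoc tests for covariate homogeneity.
* **simulate** — a synthetic-cohort generator that emulates the study
  structure: group sizes (78/58/75), per-group FIT positivity rates,
  CE log2 fold-change effects, multi-batch linear intensity drift,
  internal-standard channels, interleaved QC injections, MCAR
  missingness — with a ground-truth record for parameter recovery.
* **normalization** — linear-detection-range filtering (feature dropped
  when > 30 % of study values exceed its linear maximum), per-feature
  internal-standard selection by minimum QC RSD, robust (Theil–Sen)
  intra-batch drift correction over injection order, and rescaling so the
  batch-averaged QC calibration sample equals 1.
* **univariate** — robust fold change `log2(median_a / median_b)`,
  two-sided Wilcoxon–Mann–Whitney p-values (exact for small untied
  samples), Benjamini–Hochberg q-values per comparison, Shapiro–Wilk
  normality annotation.
* **multivariate** — NIPALS PCA with Hotelling's T² outlier screening,
  PLS-DA and OPLS-DA with 7-fold venetian-blind cross-validation
  (Q² = 1 − PRESS/SSY), CV-ANOVA model significance, variable selection by
  VIP > 1 and |p(corr)| > 0.5, and classification lists categorising
  per-sample predictions YpredPS (> 0.65 belongs, < 0.35 does not,
  borderline in between).
* **diagnostic** — chained-equation imputation with predictive mean
  matching, stratified 70/30 splits, and a 500-tree random forest
  reporting OOB error, accuracy, precision, recall, F1 and ROC-AUC for
  FIT alone versus FIT + CE panels.

Key formulas, in the field's standard notation:

* normalized abundance: `x_norm = (x / x_IS) / (a + b·t)` per batch, with
  `(a, b)` the Theil–Sen line of the IS-corrected QC calibration response
  over injection order `t`, rescaled so the per-batch QC mean is 1;
* `VIP_j = sqrt( p · Σ_a w²_ja SSY_a / Σ_a SSY_a )` (mean VIP² = 1);
* `p(corr)_j` = Pearson correlation of feature `j` with the predictive
  score vector `t₁`;
* CV-ANOVA: `F = [(SSY − PRESS)/A] / [PRESS/(N − 1 − A)]` referred to
  `F(A, N−1−A)`; `PRESS ≥ SSY ⇒ p = 1`;
* classification percentage: `100 · belongs / (belongs + not)`,
  borderline samples excluded.

## Worked example

```python
import lipidiag as ld
import lipidiag.multivariate as mv

cohort, peaks, truth = ld.simulate_study(seed=17)
normalized, model = ld.normalize(peaks)
print(f"QC_VAL median RSD: {model.qc_val_rsd.median():.1f}% "
      f"(raw: {model.qc_val_rsd_raw.median():.1f}%)")

res, _ = ld.comparison_table(normalized, cohort, [("CRC", "CTRL")])
ce = res.set_index("feature_id").loc["CE (20:4)"]
print(f"CE (20:4) CRC vs CTRL: log2 robust FC = {ce.log2_robust_fc:.3f}, "
      f"q = {ce.q_value:.2e} (injected: {truth.true_log2fc('CE (20:4)', 'CRC', 'CTRL'):.3f})")

X, _ = mv.preprocess(normalized.study_abundance(), cohort,
                     mv.PreprocessSpec(include_covariates=("fit_stand",)))
groups = cohort.group_of(X.index)
pair = groups.isin(["CRC", "CTRL"])
opls = mv.fit_oplsda(X[pair.to_numpy()], groups[pair], n_components=2,
                     cv_seed=17, positive_class="CRC")
print(f"OPLS-DA CRC vs CTRL: R2Y = {opls.r2y:.3f}, Q2 = {opls.q2:.3f}, "
      f"CV-ANOVA p = {opls.cv_anova_p:.2e}")
print(mv.select_variables(opls.vip, opls.p_corr).round(3).to_string())
```

prints

```
QC_VAL median RSD: 3.2% (raw: 15.7%)
CE (20:4) CRC vs CTRL: log2 robust FC = 2.291, q = 3.98e-20 (injected: 2.563)
OPLS-DA CRC vs CTRL: R2Y = 0.877, Q2 = 0.608, CV-ANOVA p = 2.96e-31
             vip  p_corr
CE (20:4)  5.597   0.794
CE (18:2)  5.223   0.798
```

Normalization cuts the pooled-sample QC RSD from ~16 % to ~3 %; the
injected CE(20:4) effect (2.563 log2 units) is recovered within sampling
noise and is overwhelmingly significant; the cross-validated OPLS-DA
contrast is strongly predictive, and variable selection recovers exactly
the two cholesteryl esters carrying the largest injected effects.

The same analysis runs end-to-end from the shell, writing every stage
artifact, a bit-reproducible run manifest and a markdown report:

```bash
lipidiag run --seed 7 --out-dir results/
lipidiag simulate --seed 17 --out-dir data/    # individual stages also exist:
lipidiag normalize --peaks data/peaks.csv --runs data/runs.csv \
    --features data/features.csv --out normalized.csv --model model.json
```

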