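"""Per-feature two-group statistics for normalized lipid abundances.

The metabolite distributions are typically non-normal (checked but not
gated by Shapiro-Wilk), so group contrasts use the robust fold-change
(log2 ratio of group medians) and the two-sided Wilcoxon-Mann-Whitney
rank-sum test, with Benjamini-Hochberg control of the false discovery
rate applied within each two-group comparison across features.
"""
from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import CohortTable, PeakTable

log = logging.getLogger(__name__)

EXACT_MAX_N = 20          # exact WMW enumeration up to this combined n (no ties)
MIN_GROUP_N = 3           # minimum non-missing values per group to emit a result
SIGNIFICANCE_ALPHA = 0.05


def robust_fold_change(a: Sequence[float], b: Sequence[float]) -> float:
    """log2 of median(a) / median(b); missing values dropped per group.

    Returns NaN (flagged via log) when either median is non-positive, in
    which case the feature is excluded from fold-change displays.
    """
    ma = float(np.nanmedian(np.asarray(a, float)))
    mb = float(np.nanmedian(np.asarray(b, float)))
    if not (ma > 0 and mb > 0):
        log.warning("robust_fold_change: non-positive median (%.3g / %.3g)", ma, mb)
        return np.nan
    return float(np.log2(ma / mb))


def wmw_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value.

    Uses exact enumeration of the rank-sum distribution when the combined
    sample size is at most 20 and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= EXACT_MAX_N and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """Step-up BH adjusted q-values; NaN p-values propagate as NaN."""
    p = np.asarray(p, float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def shapiro_wilk(x: Sequence[float]) -> float:
    """Shapiro-Wilk normality p-value; NaN outside 3 <= n <= 5000 or for
    constant input (annotation only -- the pipeline's tests are rank-based)."""
    x = np.asarray(x, float)
    x = x[np.isfinite(x)]
    if not 3 <= len(x) <= 5000:
        log.warning("shapiro_wilk: n=%d outside supported range", len(x))
        return np.nan
    if np.all(x == x[0]):
        log.warning("shapiro_wilk: constant sample, statistic undefined")
        return np.nan
    return float(stats.shapiro(x).pvalue)


def comparison_table(
    peaks: PeakTable,
    cohort: CohortTable,
    comparisons: Sequence[tuple[str, str]],
    alpha: float = SIGNIFICANCE_ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Univariate results for every (feature, comparison) pair.

    ``comparisons`` is a list of (group_a, group_b) pairs, e.g.
    ``[("CRC", "CTRL")]``; the fold change is median(a)/median(b).  BH
    correction runs within each comparison across features.  Returns the
    long results table and a feature x comparison log2 fold-change matrix
    (the heatmap input).  Comparisons with an absent group are skipped
    with a warning; features with fewer than 3 non-missing values in
    either group are skipped.
    """
    study = peaks.study_abundance()
    groups = cohort.group_of(study.index)
    records = []
    for ga, gb in comparisons:
        label = f"{ga}vs{gb}"
        xa = study[groups == ga]
        xb = study[groups == gb]
        if xa.empty or xb.empty:
            log.warning("comparison %s skipped: group absent", label)
            continue
        rows = []
        for f in study.columns:
            a = xa[f].dropna().to_numpy()
            b = xb[f].dropna().to_numpy()
            if len(a) < MIN_GROUP_N or len(b) < MIN_GROUP_N:
                continue
            rows.append(
                {
                    "feature_id": f,
                    "comparison": label,
                    "log2_robust_fc": robust_fold_change(a, b),
                    "p_value": wmw_test(a, b),
                    "normal_a": shapiro_wilk(a) > 0.05 if len(a) >= 3 else np.nan,
                    "normal_b": shapiro_wilk(b) > 0.05 if len(b) >= 3 else np.nan,
                }
            )
        sub = pd.DataFrame(rows)
        if not sub.empty:
            sub["q_value"] = benjamini_hochberg(sub["p_value"].to_numpy())
            sub["significant"] = sub["q_value"] < alpha
        records.append(sub)
    result = pd.concat(records, ignore_index=True) if records else pd.DataFrame(
        columns=["feature_id", "comparison", "log2_robust_fc", "p_value",
                 "normal_a", "normal_b", "q_value", "significant"]
    )
    heatmap = (
        result.pivot(index="feature_id", columns="comparison", values="log2_robust_fc")
        if not result.empty
        else pd.DataFrame()
    )
    return result, heatmap
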