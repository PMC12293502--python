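"""Linear-range filtering, internal-standard selection and QC drift correction.

The normalization chain mirrors a multi-batch targeted lipidomics workflow:

1. features whose peak areas fall outside their linear detection range in
   more than 30% of study injections are removed;
2. each remaining feature is ratioed to the internal standard (IS) that
   minimizes the relative standard deviation (RSD) of the feature/IS ratio
   over the QC calibration injections pooled across batches;
3. any residual intra-batch drift of the IS-corrected response is estimated
   by a robust (Theil-Sen) line over injection order on the QC calibration
   samples and divided out;
4. values are rescaled so that, per feature and batch, the mean corrected
   QC calibration response equals 1 -- study abundances are thereby
   expressed relative to the batch-averaged QC calibration sample;
5. reproducibility is assessed on the independent QC validation (pooled
   fecal) injections.

Blank injections are carried through untouched and excluded from every
statistic; missing values stay missing (imputation happens, if at all, just
before classifier training).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortError, PeakTable

log = logging.getLogger(__name__)

LINEAR_RANGE_MAX_FRACTION = 0.30
DEFAULT_RSD_CEILING = 30.0


def theil_sen(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Robust line fit: slope = median of pairwise slopes, intercept =
    median of ``y - slope * x``.  Deterministic, ~29% breakdown point.
    """
    a, b = _theil_sen_matrix(np.asarray(x, float), np.asarray(y, float)[:, None])
    return float(a[0]), float(b[0])


def _theil_sen_matrix(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Theil-Sen over the columns of ``Y`` (shared abscissa ``x``).

    Returns (intercepts, slopes), one per column.  Columns with fewer than
    two finite points get slope 0 and intercept = the single value (or NaN).
    """
    n = len(x)
    if n < 2:
        vals = Y[0] if n == 1 else np.full(Y.shape[1], np.nan)
        return np.asarray(vals, float), np.zeros(Y.shape[1])
    ii, jj = np.triu_indices(n, k=1)
    dx = x[jj] - x[ii]
    keep = dx != 0
    ii, jj, dx = ii[keep], jj[keep], dx[keep]
    with np.errstate(invalid="ignore"):
        slopes = (Y[jj] - Y[ii]) / dx[:, None]
        slope = np.nanmedian(slopes, axis=0)
        intercept = np.nanmedian(Y - slope[None, :] * x[:, None], axis=0)
    return intercept, slope


def estimate_drift(injection_order: np.ndarray, response: np.ndarray) -> tuple[float, float]:
    """Intra-batch drift trend of an IS-corrected QC response.

    Fits the Theil-Sen line of response versus injection order.  With fewer
    than two points the trend degenerates to a flat line at the observed
    value (slope 0), with a warning.
    """
    x = np.asarray(injection_order, float)
    y = np.asarray(response, float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        log.warning("estimate_drift: <2 QC points; falling back to identity trend")
        return (float(y[ok][0]) if ok.any() else np.nan, 0.0)
    return theil_sen(x[ok], y[ok])


def linear_range_filter(peaks: PeakTable) -> tuple[PeakTable, list[str]]:
    """Drop features outside their linear detection range too often.

    A feature is removed iff strictly more than 30% of its non-missing
    *study-sample* values exceed ``linear_max``.  Features without a
    ``linear_max`` annotation are exempt.  Internal standards are kept.
    """
    study = peaks.abundance.loc[peaks.study_ids]
    lm = pd.to_numeric(peaks.features["linear_max"], errors="coerce")
    removed: list[str] = []
    for f in peaks.assay_features:
        if not np.isfinite(lm.get(f, np.nan)):
            continue
        vals = study[f].dropna()
        if len(vals) and (vals > lm[f]).sum() / len(vals) > LINEAR_RANGE_MAX_FRACTION:
            removed.append(f)
    kept = [f for f in peaks.abundance.columns if f not in set(removed)]
    if removed:
        log.info("linear_range_filter: removed %d features", len(removed))
    return peaks.with_abundance(peaks.abundance[kept]), removed


def _rsd(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Relative standard deviation in percent (sd / mean * 100), NaN-aware."""
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.nanstd(values, axis=axis, ddof=1) / np.nanmean(values, axis=axis) * 100.0


def select_internal_standard(peaks: PeakTable, feature: str) -> tuple[str, float]:
    """Pick the IS minimizing the RSD of feature/IS over all QC_CAL samples.

    Ties are broken by lexicographic IS id.  Raises if no internal standard
    with complete QC calibration values exists (raw-mode normalization would
    then be required, which this pipeline does not implement).
    """
    table = select_all_internal_standards(peaks, [feature])
    row = table.loc[feature]
    return str(row["chosen_is"]), float(row["rsd"])


def select_all_internal_standards(peaks: PeakTable, features=None) -> pd.DataFrame:
    """Vectorized arg-min-RSD internal-standard assignment for many features."""
    is_ids = sorted(peaks.is_features)
    qc = peaks.abundance.loc[peaks.role_mask("QC_CAL")]
    is_ids = [i for i in is_ids if qc[i].notna().all() and (qc[i] > 0).all()]
    if not is_ids:
        raise CohortError(
            "no internal standard with complete QC_CAL values: "
            "use raw-mode normalization upstream of this pipeline"
        )
    feats = list(features) if features is not None else list(peaks.assay_features)
    X = qc[feats].to_numpy(float)            # (n_qc, F)
    S = qc[is_ids].to_numpy(float)           # (n_qc, K)
    ratios = X[:, :, None] / S[:, None, :]   # (n_qc, F, K)
    rsd = _rsd(ratios, axis=0)               # (F, K)
    best = np.argmin(np.where(np.isnan(rsd), np.inf, rsd), axis=1)
    return pd.DataFrame(
        {
            "chosen_is": [is_ids[k] for k in best],
            "rsd": rsd[np.arange(len(feats)), best],
        },
        index=pd.Index(feats, name="feature_id"),
    )


@dataclass
class NormalizationModel:
    """Audit record of a fitted normalization: IS choices, drift trends, RSDs."""

    chosen_is: dict                       # feature -> internal standard id
    drift_trend: dict                     # (feature, batch) -> (intercept, slope)
    qc_cal_rsd: pd.Series                 # % RSD of normalized QC_CAL values
    qc_val_rsd: pd.Series                 # % RSD of normalized QC_VAL values
    qc_val_rsd_raw: pd.Series             # % RSD of raw QC_VAL values (pre-normalization)
    retained_features: list
    removed_features: list
    drift_fallbacks: list = field(default_factory=list)  # (feature, batch) forced to slope 0
    batch_scale_stat: str = "mean"        # QC_CAL batch centring statistic

    def to_json(self, path: str | Path) -> None:
        payload = {
            "batch_scale_stat": self.batch_scale_stat,
            "chosen_is": self.chosen_is,
            "drift_trend": {f"{f}|{b}": list(v) for (f, b), v in self.drift_trend.items()},
            "qc_cal_rsd": self.qc_cal_rsd.round(6).to_dict(),
            "qc_val_rsd": self.qc_val_rsd.round(6).to_dict(),
            "qc_val_rsd_raw": self.qc_val_rsd_raw.round(6).to_dict(),
            "retained_features": list(self.retained_features),
            "removed_features": list(self.removed_features),
            "drift_fallbacks": [list(fb) for fb in self.drift_fallbacks],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def normalize(peaks: PeakTable, apply_linear_filter: bool = True) -> tuple[PeakTable, NormalizationModel]:
    """IS-ratio + QC drift correction, anchored to the QC calibration mean of 1.

    Every study/QC value becomes ``(value / chosen IS) / drift_trend(order)``,
    rescaled per (feature, batch) so the batch mean of corrected QC_CAL
    values is exactly 1.  If a fitted trend is non-positive anywhere in the
    batch's injection range, that (feature, batch) falls back to a flat
    trend (slope 0), which is logged.  Internal-standard columns are
    consumed by the correction and dropped from the output; blank injections
    are passed through unchanged.
    """
    removed: list[str] = []
    if apply_linear_filter:
        peaks, removed = linear_range_filter(peaks)

    assignment = select_all_internal_standards(peaks)
    chosen = assignment["chosen_is"]
    feats = assignment.index.to_list()

    ab = peaks.abundance
    is_values = ab[chosen.to_numpy()].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = ab[feats].to_numpy(float) / is_values
    ratio = pd.DataFrame(ratio, index=ab.index, columns=feats)

    qc_cal = peaks.role_mask("QC_CAL")
    blank = peaks.samples["sample_role"].isin(["BLANK", "SYSTEM_BLANK"])
    order = peaks.samples["injection_order"]

    normalized = ratio.copy()
    drift_trend: dict = {}
    fallbacks: list[tuple[str, str]] = []
    for batch, sub in peaks.samples.groupby("batch_id"):
        rows = sub.index
        t = order.loc[rows].to_numpy(float)
        qc_rows = rows[qc_cal.loc[rows]]
        tq = order.loc[qc_rows].to_numpy(float)
        Yq = ratio.loc[qc_rows].to_numpy(float)
        a, b = _theil_sen_matrix(tq, Yq)
        # positivity guard over the batch's injection range
        t_lo, t_hi = float(t.min()), float(t.max())
        bad = np.minimum(a + b * t_lo, a + b * t_hi) <= 0.0
        if bad.any():
            med = np.nanmedian(Yq[:, bad], axis=0)
            a[bad], b[bad] = med, 0.0
            for f in np.asarray(feats)[bad]:
                fallbacks.append((str(f), str(batch)))
            log.warning("normalize: %d non-positive drift trends in batch %s reset to flat",
                        int(bad.sum()), batch)
        trend = a[None, :] + b[None, :] * t[:, None]
        corrected = ratio.loc[rows].to_numpy(float) / trend
        qc_mean = np.nanmean(corrected[qc_cal.loc[rows].to_numpy()], axis=0)
        normalized.loc[rows] = corrected / qc_mean[None, :]
        for f, ai, bi in zip(feats, a, b):
            drift_trend[(f, str(batch))] = (float(ai), float(bi))

    # blanks pass through untouched, on the raw scale
    normalized.loc[blank] = ab.loc[blank, feats]

    qc_val = peaks.role_mask("QC_VAL")
    model = NormalizationModel(
        chosen_is=chosen.to_dict(),
        drift_trend=drift_trend,
        qc_cal_rsd=pd.Series(_rsd(normalized.loc[qc_cal].to_numpy(float)), index=feats),
        qc_val_rsd=pd.Series(_rsd(normalized.loc[qc_val].to_numpy(float)), index=feats),
        qc_val_rsd_raw=pd.Series(_rsd(ab.loc[qc_val, feats].to_numpy(float)), index=feats),
        retained_features=feats,
        removed_features=removed,
        drift_fallbacks=fallbacks,
    )
    out = peaks.with_abundance(normalized)
    return out, model


def qc_report(model: NormalizationModel, rsd_ceiling: float = DEFAULT_RSD_CEILING) -> pd.DataFrame:
    """Per-feature reproducibility table with a pass/fail RSD ceiling (%)."""
    rep = pd.DataFrame(
        {
            "chosen_is": pd.Series(model.chosen_is),
            "qc_cal_rsd": model.qc_cal_rsd,
            "qc_val_rsd": model.qc_val_rsd,
            "qc_val_rsd_raw": model.qc_val_rsd_raw,
        }
    ).loc[model.retained_features]
    rep["pass"] = rep["qc_val_rsd"] <= rsd_ceiling
    rep.index.name = "feature_id"
    return rep
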