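"""Synthetic cohorts and raw peak tables with the study's statistical structure.

The generator emulates a three-group fecal lipidomics screen: group sizes and
FIT positivity rates of the study cohort, cholesteryl-ester group effects
expressed as log2 fold-changes of group medians, multi-batch acquisition with
a linear multiplicative intensity drift over injection order, spiked
internal-standard channels whose measurement noise is shared with the
features of their lipid class, interleaved QC calibration (serum-like
reference) and QC validation (fecal pool) injections, and completely-at-
random missingness.  A :class:`SimTruth` record carries everything needed to
verify parameter recovery downstream.

Abundances are log-normal: for feature ``j`` in group ``g`` the biological
signal is ``2**(base_j + beta_{g,j} + N(0, sd_log2))`` so the true median is
exactly ``2**(base_j + beta_{g,j})`` and the configured log2 fold-change is
the log2 ratio of true group medians.  On top of the biology, each injection
carries a per-sample loading factor, a shared per-batch drift multiplier
``intercept + slope * injection_order``, an internal-standard channel noise
term shared by all features of the class, and feature-specific measurement
noise.  This is exactly the error structure that internal-standard plus
QC-drift normalization is designed to remove.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import DEFAULT_HB_THRESHOLD, GROUPS, CohortTable, PeakTable

log = logging.getLogger(__name__)

#: Observed cholesteryl-ester log2 fold-changes (AA vs CTRL, CRC vs CTRL)
#: used as the default injected effect sizes of the generator.
CE_EFFECTS_LOG2FC: dict[str, dict[str, float]] = {
    "Cholesterol and derivatives": {"AA": -0.045, "CRC": 0.012},
    "CE (18:1)": {"AA": 0.165, "CRC": 0.793},
    "CE (18:2)": {"AA": 0.395, "CRC": 1.846},
    "CE (20:2)": {"AA": 0.383, "CRC": -0.319},
    "CE (20:4)": {"AA": 0.761, "CRC": 2.563},
    "CE (20:5)": {"AA": 0.809, "CRC": 1.257},
    "CE (22:4)": {"AA": 0.054, "CRC": -0.052},
    "CE (22:5)": {"AA": 0.212, "CRC": -0.136},
    "CE (22:6)": {"AA": 0.783, "CRC": 1.057},
}

#: Spiked internal-standard channels (one per represented lipid class).
INTERNAL_STANDARDS: dict[str, str] = {
    "IS SM (d18:1/16:0)": "SM",
    "IS PE (17:0/17:0)": "PE",
    "IS PC (19:0/19:0)": "PC",
    "IS TAG (13:0/13:0/13:0)": "TG",
    "IS Cer (d18:1/17:0)": "Cer",
    "IS CE (12:0)": "CE",
}

_CLASS_TO_IS = {
    "SM": "IS SM (d18:1/16:0)",
    "PE": "IS PE (17:0/17:0)",
    "PC": "IS PC (19:0/19:0)",
    "TG": "IS TAG (13:0/13:0/13:0)",
    "DG": "IS TAG (13:0/13:0/13:0)",
    "Cer": "IS Cer (d18:1/17:0)",
    "CE": "IS CE (12:0)",
    "ST": "IS CE (12:0)",
}

_FILLER_CLASSES = ("PC", "SM", "TG", "DG", "Cer", "PE")


def _default_dict(d):
    return field(default_factory=lambda: dict(d))


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    Group sizes, FIT positivity rates, age distributions and gender mix
    default to the study cohort; effect sizes default to the cholesteryl-
    ester fold-change panel.  ``drift_slope_range`` is the relative intensity
    change per injection from which each batch draws its drift slope.
    """

    n_per_group: dict = _default_dict({"CTRL": 78, "AA": 58, "CRC": 75})
    fit_positive_rate: dict = _default_dict(
        {"CTRL": 21 / 78, "AA": 38 / 58, "CRC": 65 / 75}
    )
    age_mean: dict = _default_dict({"CTRL": 68.40, "AA": 76.69, "CRC": 77.81})
    age_sd: dict = _default_dict({"CTRL": 14.85, "AA": 9.95, "CRC": 10.74})
    pct_women: dict = _default_dict({"CTRL": 50.0, "AA": 34.0, "CRC": 29.0})
    effect_log2fc: dict = _default_dict(CE_EFFECTS_LOG2FC)
    n_features: int = 127
    n_batches: int = 3
    drift_slope_range: tuple = (-0.003, 0.003)
    qc_interval: int = 10
    missing_rate: float = 0.02
    hb_threshold: float = DEFAULT_HB_THRESHOLD
    # noise structure (log2 standard deviations)
    sd_log2: float = 1.0            # biological variance per feature
    loading_sd_log2: float = 0.20   # per-injection sample loading / response factor
    channel_sd_log2: float = 0.05   # IS-channel noise shared within a lipid class
    meas_sd_log2: float = 0.03      # residual feature-specific measurement noise
    hb_spread: float = 1.2          # log-scale spread of fecal Hb around the cut-off
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.n_per_group.items():
            if n <= 0:
                raise ValueError(f"n_per_group[{g}] must be positive (omit absent groups)")
        if not self.n_per_group:
            raise ValueError("n_per_group is empty")
        for g, p in self.fit_positive_rate.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"fit_positive_rate[{g}] outside [0, 1]")
        if self.qc_interval < 1:
            raise ValueError("qc_interval must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_features < len(self.effect_log2fc):
            raise ValueError("n_features smaller than the configured effect panel")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["drift_slope_range"] = list(self.drift_slope_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "drift_slope_range" in d:
            d["drift_slope_range"] = tuple(d["drift_slope_range"])
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth of one simulated peak table (bit-reproducible from seed)."""

    feature_medians: pd.DataFrame     # feature x group true medians
    batch_drift: dict                 # batch_id -> (intercept, slope)
    assigned_is: dict                 # feature -> intended internal standard
    missing_mask: pd.DataFrame        # sample x feature injected missingness
    qc_cal_level: pd.Series           # per-feature reference composition (QC_CAL)
    seed: int

    def true_log2fc(self, feature: str, group_a: str, group_b: str) -> float:
        m = self.feature_medians
        return float(np.log2(m.loc[feature, group_a] / m.loc[feature, group_b]))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "feature_medians": self.feature_medians.to_dict(),
            "batch_drift": {str(k): list(v) for k, v in self.batch_drift.items()},
            "assigned_is": self.assigned_is,
            "qc_cal_level": self.qc_cal_level.to_dict(),
            "n_missing": int(self.missing_mask.to_numpy().sum()),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def feature_catalogue(config: SimulationConfig) -> pd.DataFrame:
    """Feature metadata: the effect panel, synthetic filler lipids, IS channels."""
    rows = []
    for name in config.effect_log2fc:
        cls = "ST" if name.startswith("Cholesterol") else name.split(" ")[0]
        rows.append((name, cls, False))
    n_filler = config.n_features - len(rows)
    for i in range(n_filler):
        cls = _FILLER_CLASSES[i % len(_FILLER_CLASSES)]
        rows.append((f"{cls} sim-{i:03d}", cls, False))
    for is_name, cls in INTERNAL_STANDARDS.items():
        rows.append((is_name, cls, True))
    df = pd.DataFrame(rows, columns=["feature_id", "lipid_class", "is_internal_standard"])
    return df.set_index("feature_id")


def simulate_cohort(config: SimulationConfig | None = None, seed: int | None = None) -> CohortTable:
    """Draw a cohort with exact group sizes and configured FIT positivity.

    Ages are normal per group (truncated at 18 years); gender counts follow
    the configured percentage of women; fecal haemoglobin is a two-sided
    log-normal mixture around the positivity threshold in which the positive
    branch is entered with exactly the configured per-group probability.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    for group in GROUPS:
        n = int(config.n_per_group.get(group, 0))
        mu, sd = config.age_mean[group], config.age_sd[group]
        ages = mu + sd * rng.standard_normal(n)
        while (ages < 18).any():  # truncate at adulthood by redrawing
            bad = ages < 18
            ages[bad] = mu + sd * rng.standard_normal(int(bad.sum()))
        n_women = int(round(n * config.pct_women[group] / 100.0))
        gender = np.array(["F"] * n_women + ["M"] * (n - n_women))
        rng.shuffle(gender)
        positive = rng.random(n) < config.fit_positive_rate[group]
        spread = config.hb_spread * np.abs(rng.standard_normal(n))
        thr = config.hb_threshold
        hb = np.where(positive, thr * np.exp(spread), thr * np.exp(-spread) * 0.999)
        for i in range(n):
            rows.append((f"{group}-{i + 1:03d}", group, float(ages[i]), gender[i], float(hb[i])))
    df = pd.DataFrame(rows, columns=["sample_id", "group", "age", "gender", "fecal_hb"])
    return CohortTable.from_frame(df, config.hb_threshold)


def _batch_layout(study_ids: np.ndarray, config: SimulationConfig, batch: str) -> pd.DataFrame:
    """Injection sequence of one batch: blanks, interleaved QCs, study samples."""
    qi = config.qc_interval
    seq: list[tuple[str, str]] = [(f"{batch}-BLK", "BLANK"), (f"{batch}-SBLK", "SYSTEM_BLANK")]
    pending = list(study_ids)
    n_qc = {"QC_CAL": 0, "QC_VAL": 0}
    pos = 0
    while pending:
        if pos % qi == 0:
            n_qc["QC_CAL"] += 1
            seq.append((f"{batch}-QC_CAL-{n_qc['QC_CAL']:02d}", "QC_CAL"))
        elif qi > 1 and pos % qi == max(1, qi // 2):
            n_qc["QC_VAL"] += 1
            seq.append((f"{batch}-QC_VAL-{n_qc['QC_VAL']:02d}", "QC_VAL"))
        else:
            seq.append((pending.pop(0), "STUDY"))
        pos += 1
    for role in ("QC_CAL", "QC_VAL"):  # closing QCs bracket the batch
        n_qc[role] += 1
        seq.append((f"{batch}-{role}-{n_qc[role]:02d}", role))
    df = pd.DataFrame(seq, columns=["sample_id", "sample_role"])
    df["batch_id"] = batch
    df["injection_order"] = np.arange(1, len(df) + 1)
    return df


def simulate_peak_table(
    cohort: CohortTable, config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[PeakTable, SimTruth]:
    """Simulate raw peak areas for a cohort, returning the table and its truth.

    Study samples are randomized across batches; each batch is acquired with
    its own linear drift multiplier shared by every feature (including the
    internal standards, which is what makes IS-ratio correction effective).
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)

    feats = feature_catalogue(config)
    feature_ids = feats.index.to_numpy()
    is_mask = feats["is_internal_standard"].to_numpy(bool)
    n_feat = len(feats)

    # batch assignment of study samples
    study = cohort.sample_ids.to_numpy().copy()
    rng.shuffle(study)
    parts = np.array_split(study, config.n_batches)
    min_per_batch = config.qc_interval + 1
    if any(len(p) < min_per_batch for p in parts):
        raise ValueError("more QC samples requested than injections available per batch")
    layout = pd.concat(
        [_batch_layout(p, config, f"B{i + 1}") for i, p in enumerate(parts)], ignore_index=True
    ).set_index("sample_id")

    # ground-truth composition
    base_log2 = rng.normal(17.0, 1.5, n_feat)
    beta = pd.DataFrame(0.0, index=feature_ids, columns=list(GROUPS))
    for f, eff in config.effect_log2fc.items():
        for g, b in eff.items():
            beta.loc[f, g] = float(b)
    qc_cal_level = base_log2 + rng.normal(0.0, 0.5, n_feat)   # serum-like reference
    weights = np.array([config.n_per_group.get(g, 0) for g in GROUPS], float)
    pooled_offset = np.log2((2.0 ** beta.to_numpy() @ weights) / weights.sum())
    qc_val_level = base_log2 + pooled_offset                   # fecal pool
    is_channel = feats["lipid_class"].map(_CLASS_TO_IS).fillna("IS PC (19:0/19:0)")
    is_channel[feats.index[is_mask]] = feats.index[is_mask]    # an IS tracks its own channel
    channel_names = list(INTERNAL_STANDARDS)
    channel_idx = is_channel.map({c: i for i, c in enumerate(channel_names)}).to_numpy()

    # per-batch drift
    lo, hi = config.drift_slope_range
    batch_drift: dict[str, tuple[float, float]] = {}
    for batch, sub in layout.groupby("batch_id"):
        slope = float(rng.uniform(lo, hi))
        mid = float(sub["injection_order"].mean())
        intercept = 1.0 - slope * mid
        t = sub["injection_order"].to_numpy()
        if ((intercept + slope * t) <= 0.05).any():
            raise ValueError(f"batch {batch}: drift slope leaves non-positive trend")
        batch_drift[batch] = (intercept, slope)

    # assemble the signal in log2 space, then apply the multiplicative drift
    n_samp = len(layout)
    log2m = np.empty((n_samp, n_feat))
    group_lookup = cohort.data["group"]
    roles = layout["sample_role"].to_numpy()
    for i, (sid, role) in enumerate(zip(layout.index, roles)):
        if role == "STUDY":
            g = group_lookup[sid]
            log2m[i] = base_log2 + beta[g].to_numpy() + rng.normal(0.0, config.sd_log2, n_feat)
        elif role == "QC_CAL":
            log2m[i] = qc_cal_level
        elif role == "QC_VAL":
            log2m[i] = qc_val_level
        else:  # blanks: trace-level noise only
            log2m[i] = base_log2 - 12.0 + rng.normal(0.0, 0.5, n_feat)
    log2m[:, is_mask] = base_log2[is_mask]  # IS spiked at nominal level everywhere

    loading = rng.normal(0.0, config.loading_sd_log2, n_samp)
    channel_noise = rng.normal(0.0, config.channel_sd_log2, (n_samp, len(channel_names)))
    meas = rng.normal(0.0, config.meas_sd_log2, (n_samp, n_feat))
    log2m += loading[:, None] + channel_noise[:, channel_idx] + meas

    drift = np.empty(n_samp)
    for batch, (a, b) in batch_drift.items():
        m = (layout["batch_id"] == batch).to_numpy()
        drift[m] = a + b * layout.loc[m, "injection_order"].to_numpy()
    values = (2.0 ** log2m) * drift[:, None]

    abundance = pd.DataFrame(values, index=layout.index, columns=feature_ids)
    missing = pd.DataFrame(False, index=layout.index, columns=feature_ids)
    study_rows = roles == "STUDY"
    mcar = rng.random((int(study_rows.sum()), n_feat)) < config.missing_rate
    mcar[:, is_mask] = False
    missing.loc[study_rows] = mcar
    abundance = abundance.mask(missing)

    feats = feats.copy()
    feats["linear_max"] = 2.0 ** (base_log2 + 6.0)  # generous linear range
    table = PeakTable(abundance, layout[["batch_id", "injection_order", "sample_role"]], feats)
    medians = pd.DataFrame(
        {g: 2.0 ** (base_log2 + beta[g].to_numpy()) for g in GROUPS}, index=feature_ids
    )
    truth = SimTruth(
        feature_medians=medians,
        batch_drift=batch_drift,
        assigned_is=is_channel.to_dict(),
        missing_mask=missing,
        qc_cal_level=pd.Series(qc_cal_level, index=feature_ids),
        seed=int(config.seed + 1 if seed is None else seed),
    )
    return table, truth


def simulate_study(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[CohortTable, PeakTable, SimTruth]:
    """Cohort plus peak table from a single seed (split into child streams)."""
    config = config or SimulationConfig()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    s_cohort, s_peaks = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(2)]
    cohort = simulate_cohort(config, seed=s_cohort)
    table, truth = simulate_peak_table(cohort, config, seed=s_peaks)
    return cohort, table, truth
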