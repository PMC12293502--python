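"""Cohort metadata, peak-table containers and group-homogeneity statistics.

The study design compares three colonoscopy-confirmed groups -- healthy
controls (CTRL), advanced adenoma (AA) and colorectal cancer (CRC) --
profiled by targeted fecal lipidomics alongside the fecal immunochemical
test (FIT).  A FIT result is positive when fecal haemoglobin reaches the
screening threshold (20 ug Hb / g feces; the comparison is inclusive).

Group homogeneity of clinical covariates (age, gender, fecal Hb) is tested
with one-way ANOVA plus a Brown-Forsythe (median-centred) Levene test; as
variances are typically heterogeneous, pairwise differences are located with
the Games-Howell post hoc test (Welch-Satterthwaite degrees of freedom and
the studentized-range distribution).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

GROUPS = ("CTRL", "AA", "CRC")
GENDERS = ("F", "M")
SAMPLE_ROLES = ("STUDY", "QC_CAL", "QC_VAL", "BLANK", "SYSTEM_BLANK")
DEFAULT_HB_THRESHOLD = 20.0

COHORT_COLUMNS = ("sample_id", "group", "age", "gender", "fecal_hb")
RUN_COLUMNS = ("sample_id", "batch_id", "injection_order", "sample_role")
FEATURE_COLUMNS = ("feature_id", "lipid_class", "is_internal_standard", "linear_max")


class CohortError(ValueError):
    """Raised when cohort or peak-table inputs violate their contract."""


def derive_fit_status(fecal_hb: pd.Series, hb_threshold: float = DEFAULT_HB_THRESHOLD) -> pd.Series:
    """FIT positivity: positive iff fecal Hb >= threshold (inclusive).

    Missing haemoglobin yields a missing FIT status (nullable boolean).
    """
    if hb_threshold <= 0:
        raise CohortError(f"hb_threshold must be positive, got {hb_threshold}")
    out = pd.Series(pd.NA, index=fecal_hb.index, dtype="boolean")
    obs = fecal_hb.notna()
    out[obs] = fecal_hb[obs] >= hb_threshold
    return out


@dataclass(frozen=True)
class CohortTable:
    """Per-sample clinical metadata with derived FIT status.

    ``data`` is indexed by unique sample id and carries columns
    ``group`` (CTRL/AA/CRC), ``age`` (years), ``gender`` (F/M),
    ``fecal_hb`` (ug Hb/g feces, may be missing) and ``fit_positive``
    (nullable boolean derived from ``fecal_hb``).
    """

    data: pd.DataFrame
    hb_threshold: float = DEFAULT_HB_THRESHOLD

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise CohortError(f"duplicate sample_id values: {dupes}")
        missing = {"group", "age", "gender", "fecal_hb", "fit_positive"} - set(df.columns)
        if missing:
            raise CohortError(f"cohort table lacks columns: {sorted(missing)}")
        bad_groups = set(df["group"].unique()) - set(GROUPS)
        if bad_groups:
            raise CohortError(f"unknown group labels: {sorted(bad_groups)}")
        if (df["age"].dropna() <= 0).any():
            raise CohortError("ages must be positive")
        if (df["fecal_hb"].dropna() < 0).any():
            raise CohortError("fecal_hb must be non-negative")
        expected = derive_fit_status(df["fecal_hb"], self.hb_threshold)
        got = df["fit_positive"].astype("boolean")
        obs = df["fecal_hb"].notna()
        if not got[obs].equals(expected[obs]):
            raise CohortError("fit_positive inconsistent with fecal_hb and threshold")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, hb_threshold: float = DEFAULT_HB_THRESHOLD) -> "CohortTable":
        """Build from a frame with the raw cohort columns; derives FIT status."""
        df = df.copy()
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        df["group"] = df["group"].astype(str).str.strip().str.upper()
        df["fecal_hb"] = pd.to_numeric(df["fecal_hb"], errors="coerce")
        df["fit_positive"] = derive_fit_status(df["fecal_hb"], hb_threshold)
        return cls(df[["group", "age", "gender", "fecal_hb", "fit_positive"]], hb_threshold)

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def group_of(self, sample_ids: Sequence[str]) -> pd.Series:
        return self.data.loc[list(sample_ids), "group"]

    def to_csv(self, path: str | Path) -> None:
        out = self.data.reset_index().rename(columns={"index": "sample_id"})
        out.to_csv(path, index=False)


def load_cohort(path: str | Path, hb_threshold: float = DEFAULT_HB_THRESHOLD) -> CohortTable:
    """Read a delimited cohort metadata file and derive FIT positivity.

    Rows whose group label cannot be parsed into CTRL/AA/CRC are rejected
    (dropped with a warning); duplicate sample ids are a hard error; samples
    without a fecal Hb value keep a missing FIT status and are logged.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise CohortError(f"{path}: missing required columns {sorted(missing)}")
    df["group"] = df["group"].astype(str).str.strip().str.upper()
    bad = ~df["group"].isin(GROUPS)
    if bad.any():
        log.warning("%s: rejecting %d rows with unparseable group labels", path, int(bad.sum()))
        df = df[~bad]
    dup = df["sample_id"].duplicated()
    if dup.any():
        raise CohortError(f"{path}: duplicate sample_id {sorted(df.loc[dup, 'sample_id'].unique())}")
    n_missing_hb = int(df["fecal_hb"].isna().sum())
    if n_missing_hb:
        log.warning("%s: %d samples lack fecal_hb; FIT status left missing", path, n_missing_hb)
    return CohortTable.from_frame(df, hb_threshold)


def cohort_summary(cohort: CohortTable) -> pd.DataFrame:
    """Per-group descriptive statistics in study-table layout.

    Returns one row per group (CTRL, AA, CRC) with sample count, percentage
    of women, age mean +/- sd, FIT(+)/FIT(-) counts and the within-group FIT
    positive/negative percentages.  Percentages are computed from the counts
    of samples with a known FIT status; an empty group is reported with N=0
    and undefined (NaN) percentages.
    """
    rows = []
    df = cohort.data
    for group in GROUPS:
        sub = df[df["group"] == group]
        n = len(sub)
        fit = sub["fit_positive"].dropna()
        n_pos = int(fit.sum())
        n_neg = int((~fit.astype(bool)).sum())
        known = n_pos + n_neg
        rows.append(
            {
                "group": group,
                "n": n,
                "pct_women": 100.0 * (sub["gender"] == "F").sum() / n if n else np.nan,
                "age_mean": sub["age"].mean() if n else np.nan,
                "age_sd": sub["age"].std(ddof=1) if n > 1 else np.nan,
                "n_fit_positive": n_pos,
                "n_fit_negative": n_neg,
                "fit_positive_pct": 100.0 * n_pos / known if known else np.nan,
                "fit_negative_pct": 100.0 * n_neg / known if known else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("group")


@dataclass(frozen=True)
class GroupComparisonStat:
    """One-way ANOVA + Levene + Games-Howell pairwise results for a variable."""

    variable: str
    anova_p: float
    levene_p: float
    pairwise: tuple  # of (group_a, group_b, games_howell_p)
    degenerate: bool = False  # all groups had zero within-group variance

    def pairwise_p(self, a: str, b: str) -> float:
        for ga, gb, p in self.pairwise:
            if {ga, gb} == {a, b}:
                return p
        raise KeyError((a, b))


def games_howell(samples: Mapping[str, np.ndarray]) -> list[tuple[str, str, float]]:
    """Games-Howell pairwise comparisons for unequal variances.

    For each pair, the Welch t statistic is referred to the studentized-range
    distribution with k = number of groups and Welch-Satterthwaite degrees of
    freedom (q = t * sqrt(2)).  At k = 2 this reduces exactly to Welch's
    two-sided t-test.
    """
    k = len(samples)
    stats_ = {
        g: (len(x), float(np.mean(x)), float(np.var(x, ddof=1)))
        for g, x in ((g, np.asarray(x, dtype=float)) for g, x in samples.items())
    }
    out = []
    for a, b in combinations(samples, 2):
        na, ma, va = stats_[a]
        nb, mb, vb = stats_[b]
        se2 = va / na + vb / nb
        if se2 == 0.0:
            out.append((a, b, 1.0))
            continue
        t = abs(ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = float(stats.studentized_range.sf(t * np.sqrt(2.0), k, df))
        out.append((a, b, min(1.0, max(0.0, p))))
    return out


def group_difference_test(values: Sequence[float], groups: Sequence[str], variable: str = "value") -> GroupComparisonStat:
    """Test a clinical variable for differences among groups.

    One-way ANOVA F-test, Brown-Forsythe Levene test (median-centred) and
    Games-Howell pairwise p-values.  Requires >=2 groups with >=2
    observations each; if every group has zero within-group variance the
    ANOVA is undefined and the result is flagged ``degenerate``.
    """
    s = pd.DataFrame({"v": pd.to_numeric(pd.Series(list(values)), errors="coerce"),
                      "g": list(groups)}).dropna()
    arrays = {g: sub["v"].to_numpy() for g, sub in s.groupby("g", sort=False)}
    arrays = {g: a for g, a in arrays.items() if len(a) >= 2}
    if len(arrays) < 2:
        raise CohortError("need >=2 groups with >=2 observations each")
    if all(np.var(a) == 0.0 for a in arrays.values()):
        log.warning("%s: zero within-group variance in all groups; ANOVA undefined", variable)
        return GroupComparisonStat(variable, np.nan, np.nan, tuple(), degenerate=True)
    anova_p = float(stats.f_oneway(*arrays.values()).pvalue)
    levene_p = float(stats.levene(*arrays.values(), center="median").pvalue)
    pairs = tuple(games_howell(arrays))
    return GroupComparisonStat(variable, anova_p, levene_p, pairs)


# ---------------------------------------------------------------------------
# Peak table container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeakTable:
    """Samples x features peak-area matrix with run and feature annotations.

    ``abundance``: non-negative areas (missing allowed), indexed by sample id.
    ``samples``:   per-sample ``batch_id``, ``injection_order``, ``sample_role``.
    ``features``:  per-feature ``lipid_class``, ``is_internal_standard``,
                   ``linear_max`` (upper end of the linear detection range,
                   may be missing = exempt from range filtering).
    """

    abundance: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame

    def __post_init__(self) -> None:
        ab, sm, ft = self.abundance, self.samples, self.features
        if not ab.index.equals(sm.index):
            raise CohortError("abundance and sample annotations must share an index")
        if not ab.columns.equals(ft.index):
            raise CohortError("abundance columns must match feature annotations")
        if (ab.to_numpy(dtype=float, na_value=np.nan) < 0).any():
            raise CohortError("negative abundances are not allowed")
        bad_roles = set(sm["sample_role"].unique()) - set(SAMPLE_ROLES)
        if bad_roles:
            raise CohortError(f"unknown sample roles: {sorted(bad_roles)}")
        for batch, sub in sm.groupby("batch_id"):
            if (sub["sample_role"] == "QC_CAL").sum() < 2:
                raise CohortError(f"batch {batch!r} has fewer than 2 QC_CAL injections")
            inj = sub["injection_order"]
            if inj.duplicated().any() or (inj <= 0).any():
                raise CohortError(f"batch {batch!r}: injection_order must be unique positive integers")

    # -- convenience views ---------------------------------------------------

    def role_mask(self, role: str) -> pd.Series:
        return self.samples["sample_role"] == role

    @property
    def study_ids(self) -> pd.Index:
        return self.samples.index[self.role_mask("STUDY")]

    @property
    def is_features(self) -> pd.Index:
        return self.features.index[self.features["is_internal_standard"].astype(bool)]

    @property
    def assay_features(self) -> pd.Index:
        """Features eligible as study biomarkers (never internal standards)."""
        return self.features.index[~self.features["is_internal_standard"].astype(bool)]

    @property
    def batches(self) -> list:
        return list(pd.unique(self.samples["batch_id"]))

    def study_abundance(self) -> pd.DataFrame:
        return self.abundance.loc[self.study_ids, self.assay_features]

    def with_abundance(self, abundance: pd.DataFrame, features: pd.DataFrame | None = None) -> "PeakTable":
        return PeakTable(abundance, self.samples.loc[abundance.index],
                         self.features.loc[abundance.columns] if features is None else features)

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_csvs(cls, peaks: str | Path, runs: str | Path, features: str | Path) -> "PeakTable":
        ab = pd.read_csv(peaks, sep=None, engine="python")
        ab = ab.set_index(ab.columns[0])
        ab.index = ab.index.astype(str)
        ab.index.name = "sample_id"
        sm = pd.read_csv(runs, sep=None, engine="python").set_index("sample_id")
        sm.index = sm.index.astype(str)
        ft = pd.read_csv(features, sep=None, engine="python").set_index("feature_id")
        ft["is_internal_standard"] = ft["is_internal_standard"].astype(bool)
        return cls(ab.loc[sm.index, ft.index.tolist()], sm, ft)

    def to_csvs(self, peaks: str | Path, runs: str | Path, features: str | Path) -> None:
        self.abundance.rename_axis("sample_id").to_csv(peaks)
        self.samples.rename_axis("sample_id").to_csv(runs)
        self.features.rename_axis("feature_id").to_csv(features)
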