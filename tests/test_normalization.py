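"""Linear-range filtering, IS selection, Theil-Sen drift and normalization."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lipidiag as ld
from lipidiag.normalization import (
    _rsd,
    _theil_sen_matrix,
    estimate_drift,
    linear_range_filter,
    qc_report,
    select_internal_standard,
    theil_sen,
)
from lipidiag.simulate import SimulationConfig

from conftest import make_peak_table


def _meta(names, linear_max=None, is_flags=None):
    n = len(names)
    return pd.DataFrame(
        {
            "lipid_class": ["CE"] * n,
            "is_internal_standard": is_flags or [False] * n,
            "linear_max": linear_max or [np.nan] * n,
        },
        index=pd.Index(names, name="feature_id"),
    )


class TestLinearRangeFilter:
    @pytest.mark.parametrize("n_above,removed", [(31, True), (30, False)])
    def test_thirty_percent_rule_is_strict(self, n_above, removed):
        vals = np.full((100, 2), 10.0)
        vals[:n_above, 0] = 99.0  # above the linear maximum
        meta = _meta(["f1", "f2", "is1"], linear_max=[50.0, 50.0, np.nan],
                     is_flags=[False, False, True])
        peaks = make_peak_table(np.column_stack([vals, np.full(100, 5.0)]), meta)
        filtered, out = linear_range_filter(peaks)
        assert ("f1" in out) == removed
        assert "f2" not in out

    def test_feature_without_linear_max_exempt(self):
        meta = _meta(["f1", "is1"], linear_max=[np.nan, np.nan], is_flags=[False, True])
        vals = np.column_stack([np.full(50, 1e9), np.full(50, 5.0)])
        _, out = linear_range_filter(make_peak_table(vals, meta))
        assert out == []

    def test_qc_samples_not_counted(self):
        """Only study-sample values count toward the 30% rule."""
        meta = _meta(["f1", "is1"], linear_max=[50.0, np.nan], is_flags=[False, True])
        study = np.column_stack([np.full(10, 10.0), np.full(10, 5.0)])
        peaks = make_peak_table(study, meta, n_qc=3)
        ab = peaks.abundance.copy()
        ab.loc[peaks.role_mask("QC_CAL"), "f1"] = 999.0  # QC way above linear_max
        _, out = linear_range_filter(ld.PeakTable(ab, peaks.samples, peaks.features))
        assert out == []


class TestTheilSen:
    def test_exact_line(self):
        x = np.arange(10.0)
        a, b = theil_sen(x, 1.0 + 0.01 * x)
        assert a == pytest.approx(1.0, abs=1e-12)
        assert b == pytest.approx(0.01, abs=1e-12)

    def test_constant_series_slope_zero(self):
        a, b = theil_sen(np.arange(8.0), np.full(8, 3.0))
        assert (a, b) == (3.0, 0.0)

    def test_robust_to_gross_outlier(self, rng):
        x = np.arange(10.0)
        y = 2.0 + 0.5 * x
        ls_clean = np.polyfit(x, y, 1)[0]
        y_out = y.copy()
        y_out[9] = 100.0  # leverage point at the end of the series
        _, b = theil_sen(x, y_out)
        assert b == pytest.approx(ls_clean, rel=0.10)
        # plain least squares is destroyed by the same outlier
        assert abs(np.polyfit(x, y_out, 1)[0] - ls_clean) > 1.0

    def test_matches_scipy_joint_method(self, rng):
        for _ in range(5):
            x = rng.uniform(0, 50, 15)
            y = rng.normal(2 + 0.3 * x, 1.0)
            ref = stats.theilslopes(y, x, method="joint")
            a, b = theil_sen(x, y)
            assert b == pytest.approx(ref.slope, abs=1e-12)
            assert a == pytest.approx(ref.intercept, abs=1e-12)

    def test_fewer_than_two_points_falls_back(self):
        a, b = estimate_drift(np.array([4.0]), np.array([2.5]))
        assert (a, b) == (2.5, 0.0)

    def test_slope_recovery_within_three_standard_errors(self, rng):
        """On noisy lines, the Theil-Sen slope lies within 3 least-squares
        standard errors of truth for >=95% of cells."""
        x = np.arange(1.0, 13.0)
        se = 0.05 / np.sqrt(((x - x.mean()) ** 2).sum())
        ok = 0
        for _ in range(200):
            y = 1.0 + 0.01 * x + rng.normal(0, 0.05, len(x))
            _, b = theil_sen(x, y)
            ok += abs(b - 0.01) <= 3 * se
        assert ok / 200 >= 0.95


class TestInternalStandardSelection:
    def _two_is_table(self, rng, proportional_to="is_a"):
        names = ["feat", "is_a", "is_b"]
        meta = _meta(names, is_flags=[False, True, True])
        n = 12
        is_a = np.exp(rng.normal(0, 0.2, n)) * 100
        is_b = np.exp(rng.normal(0, 0.2, n)) * 80
        feat = 3.0 * (is_a if proportional_to == "is_a" else is_b)
        ab = pd.DataFrame({"feat": feat, "is_a": is_a, "is_b": is_b},
                          index=[f"q{i}" for i in range(n)])
        samples = pd.DataFrame({"batch_id": "B1", "injection_order": range(1, n + 1),
                                "sample_role": ["QC_CAL"] * n}, index=ab.index)
        return ld.PeakTable(ab, samples, meta)

    def test_proportional_noise_cancels_exactly(self, rng):
        peaks = self._two_is_table(rng, proportional_to="is_a")
        chosen, rsd = select_internal_standard(peaks, "feat")
        assert chosen == "is_a"
        assert rsd == pytest.approx(0.0, abs=1e-9)

    def test_argmin_matches_bruteforce_enumeration(self, rng):
        peaks = self._two_is_table(rng, proportional_to="is_b")
        qc = peaks.abundance
        rsds = {}
        for cand in ("is_a", "is_b"):
            ratio = qc["feat"] / qc[cand]
            rsds[cand] = ratio.std(ddof=1) / ratio.mean() * 100
        chosen, rsd = select_internal_standard(peaks, "feat")
        assert chosen == min(rsds, key=rsds.get)
        assert rsd == pytest.approx(min(rsds.values()), abs=1e-9)

    def test_single_candidate_always_chosen(self, rng):
        names = ["feat", "only_is"]
        meta = _meta(names, is_flags=[False, True])
        ab = pd.DataFrame(rng.uniform(10, 20, (6, 2)), columns=names,
                          index=[f"q{i}" for i in range(6)])
        samples = pd.DataFrame({"batch_id": "B1", "injection_order": range(1, 7),
                                "sample_role": ["QC_CAL"] * 6}, index=ab.index)
        chosen, _ = select_internal_standard(ld.PeakTable(ab, samples, meta), "feat")
        assert chosen == "only_is"

    def test_no_internal_standard_raises(self, rng):
        meta = _meta(["feat"], is_flags=[False])
        peaks = make_peak_table(rng.uniform(1, 2, (6, 1)), meta)
        with pytest.raises(Exception, match="raw-mode"):
            select_internal_standard(peaks, "feat")


class TestNormalize:
    def test_qc_cal_batch_means_are_one(self, normalized_study):
        _, normalized, _, _ = normalized_study
        qc = normalized.abundance.loc[normalized.role_mask("QC_CAL")]
        batches = normalized.samples.loc[qc.index, "batch_id"]
        assert np.abs(qc.groupby(batches).mean() - 1.0).to_numpy().max() < 1e-9

    def test_zero_noise_drift_removed_exactly(self):
        cfg = SimulationConfig(
            n_per_group={"CTRL": 20, "AA": 10, "CRC": 20}, n_features=15,
            n_batches=1, qc_interval=5, drift_slope_range=(0.003, 0.003),
            loading_sd_log2=0.0, channel_sd_log2=0.0, meas_sd_log2=0.0,
            missing_rate=0.0,
        )
        cohort = ld.simulate_cohort(cfg, seed=5)
        peaks, _ = ld.simulate_peak_table(cohort, cfg, seed=6)
        _, model = ld.normalize(peaks)
        assert (model.qc_cal_rsd.abs() < 1e-9).all()

    def test_qc_val_rsd_decreases_for_nearly_all_features(self, normalized_study):
        _, _, model, _ = normalized_study
        improved = (model.qc_val_rsd < model.qc_val_rsd_raw).mean()
        assert improved >= 0.95

    def test_scale_equivariance_of_chosen_ratio(self, small_config):
        """Multiplying a feature and its chosen IS by the same per-sample
        factors leaves that feature's normalized study values unchanged."""
        cohort = ld.simulate_cohort(small_config, seed=8)
        peaks, _ = ld.simulate_peak_table(cohort, small_config, seed=9)
        norm1, model1 = ld.normalize(peaks)
        feat = model1.retained_features[0]
        is_id = model1.chosen_is[feat]
        factors = np.exp(np.random.default_rng(0).normal(0, 0.5, len(peaks.abundance)))
        ab = peaks.abundance.copy()
        ab[feat] = ab[feat] * factors
        ab[is_id] = ab[is_id] * factors
        norm2, model2 = ld.normalize(ld.PeakTable(ab, peaks.samples, peaks.features))
        assert model2.chosen_is[feat] == is_id
        pd.testing.assert_series_equal(
            norm1.abundance.loc[norm1.study_ids, feat],
            norm2.abundance.loc[norm2.study_ids, feat],
        )

    def test_blanks_pass_through_untouched(self, default_study, normalized_study):
        _, peaks, _ = default_study
        _, normalized, model, _ = normalized_study
        blanks = peaks.samples["sample_role"].isin(["BLANK", "SYSTEM_BLANK"])
        raw = peaks.abundance.loc[blanks, model.retained_features]
        pd.testing.assert_frame_equal(normalized.abundance.loc[blanks], raw)


class TestQcReport:
    def test_rsd_matches_direct_formula(self, normalized_study):
        _, normalized, model, _ = normalized_study
        qc_val = normalized.abundance.loc[normalized.role_mask("QC_VAL")]
        direct = qc_val.std(ddof=1) / qc_val.mean() * 100.0
        assert np.allclose(model.qc_val_rsd, direct[model.retained_features], atol=1e-9)

    def test_failing_feature_listed_exactly_once(self, normalized_study):
        _, _, model, _ = normalized_study
        rep = qc_report(model, rsd_ceiling=model.qc_val_rsd.median())
        failing = rep.index[~rep["pass"]]
        assert failing.is_unique and len(failing) > 0
        assert (rep.loc[failing, "qc_val_rsd"] > model.qc_val_rsd.median()).all()

    def test_zero_noise_all_pass(self):
        cfg = SimulationConfig(
            n_per_group={"CTRL": 15, "AA": 10, "CRC": 15}, n_features=10,
            n_batches=1, qc_interval=5, loading_sd_log2=0.0,
            channel_sd_log2=0.0, meas_sd_log2=0.0, missing_rate=0.0,
        )
        cohort = ld.simulate_cohort(cfg, seed=3)
        peaks, _ = ld.simulate_peak_table(cohort, cfg, seed=4)
        _, model = ld.normalize(peaks)
        rep = qc_report(model)
        assert rep["pass"].all()
        assert (rep["qc_cal_rsd"].abs() < 1e-9).all()
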