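"""NIPALS chemometrics: PCA/SVD agreement, OPLS structure, VIP, p(corr),
CV-ANOVA behaviour and classification-list arithmetic."""
import numpy as np
import pandas as pd
import pytest

import lipidiag.multivariate as mv


def _frame(arr, prefix="x"):
    return pd.DataFrame(arr, index=[f"s{i}" for i in range(arr.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


def _stub_model(press, ssy, n=30, a=2):
    idx = pd.Index([f"s{i}" for i in range(n)])
    return mv.LatentModel(
        kind="PLSDA", scores=pd.DataFrame(index=idx), loadings=pd.DataFrame(),
        r2x=0.0, n_components=a, sample_ids=idx, feature_names=pd.Index([]),
        press=press, ssy=ssy,
    )


class TestPreprocess:
    def test_autoscaled_columns_standardized(self, rng):
        X = _frame(rng.lognormal(2, 1, (40, 6)))
        Z, _ = mv.preprocess(X)
        assert np.allclose(Z.mean(), 0.0, atol=1e-9)
        assert np.allclose(Z.std(ddof=1), 1.0, atol=1e-9)

    def test_constant_feature_becomes_zero_column(self, rng):
        X = _frame(rng.lognormal(0, 1, (20, 3)))
        X["x0"] = 7.0
        Z, _ = mv.preprocess(X)
        assert np.allclose(Z["x0"], 0.0)

    def test_covariate_median_exactly_zero(self, normalized_study):
        cohort, normalized, _, _ = normalized_study
        Z, _ = mv.preprocess(
            normalized.study_abundance(), cohort,
            mv.PreprocessSpec(include_covariates=("age_stand", "fit_stand")),
        )
        assert Z["age_stand"].median() == 0.0
        assert Z["fit_stand"].median() == 0.0
        assert Z["age_stand"].std(ddof=1) == pytest.approx(1.0)

    def test_zero_values_get_half_minimum_offset(self):
        X = _frame(np.array([[0.0, 4.0], [2.0, 8.0], [4.0, 16.0]]))
        Z, fit = mv.preprocess(X, spec=mv.PreprocessSpec(autoscale=False))
        assert Z.iloc[0, 0] == pytest.approx(np.log2(1.0))  # half of min positive (2.0)


class TestPCA:
    def test_matches_svd_on_complete_matrix(self, rng):
        X = _frame(rng.standard_normal((30, 8)))
        model = mv.fit_pca(X, n_components=3)
        Xc = X - X.mean()
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        for a in range(3):
            p = model.loadings.iloc[:, a].to_numpy()
            cos = abs(p @ Vt[a]) / np.linalg.norm(p)
            assert cos >= 1 - 1e-6
        # explained variance per component matches singular values
        r2_svd = s[:3] ** 2 / (s**2).sum()
        assert np.allclose(model.r2x_per_component, r2_svd, atol=1e-6)

    def test_rank_one_matrix_fully_explained(self, rng):
        X = _frame(np.outer(rng.standard_normal(12), rng.standard_normal(5)))
        model = mv.fit_pca(X, n_components=1)
        assert model.r2x_per_component[0] == pytest.approx(1.0, abs=1e-9)

    def test_scores_mutually_orthogonal(self, rng):
        X = _frame(rng.standard_normal((25, 10)))
        T = mv.fit_pca(X, n_components=4).scores.to_numpy()
        for i in range(4):
            for j in range(i + 1, 4):
                bound = 1e-6 * np.linalg.norm(T[:, i]) * np.linalg.norm(T[:, j])
                assert abs(T[:, i] @ T[:, j]) <= bound

    def test_all_missing_column_rejected(self, rng):
        X = _frame(rng.standard_normal((10, 3)))
        X["x1"] = np.nan
        with pytest.raises(ValueError, match="all-missing"):
            mv.fit_pca(X, 1)


class TestHotellingT2:
    def test_limit_matches_two_component_closed_form(self):
        from scipy import stats
        n = 50
        expected = 2 * (n - 1) * (n + 1) / (n * (n - 2)) * stats.f.ppf(0.95, 2, n - 2)
        assert mv.t2_limit(n, 2, 0.05) == pytest.approx(expected, rel=1e-12)

    def test_planted_outlier_flagged(self, rng):
        X = rng.standard_normal((60, 5))
        X[0] += 10.0  # translate one sample far along the feature axes
        model = mv.fit_pca(_frame(X), 2)
        assert "s0" in mv.detect_outliers(model, 0.05)

    def test_alpha_one_flags_nothing(self, rng):
        model = mv.fit_pca(_frame(rng.standard_normal((20, 4))), 2)
        assert mv.detect_outliers(model, 1.0) == []

    def test_false_positive_rate_near_alpha(self, rng):
        rates = []
        for _ in range(40):
            model = mv.fit_pca(_frame(rng.standard_normal((100, 4))), 2)
            rates.append(len(mv.detect_outliers(model, 0.05)) / 100)
        assert 0.02 <= np.mean(rates) <= 0.09


class TestPLSDA:
    def test_separable_classes_have_high_q2(self, rng):
        X = rng.standard_normal((40, 10))
        X[:20, 0] += 5.0
        model = mv.fit_plsda(_frame(X), ["A"] * 20 + ["B"] * 20, 2, cv_seed=0)
        assert model.q2 > 0.5
        assert model.cv_anova_p < 1e-6

    def test_permuted_labels_destroy_q2(self, rng):
        X = rng.standard_normal((40, 10))
        X[:20, 0] += 5.0
        labels = np.array(["A"] * 20 + ["B"] * 20)
        bad = 0
        for i in range(30):
            perm = rng.permutation(labels)
            m = mv.fit_plsda(_frame(X), perm, 2, cv_seed=i)
            bad += m.q2 <= 0
        assert bad >= 27  # >= 90% of permutations

    def test_single_predictor_equals_least_squares(self, rng):
        """One component on one predictor is classical regression up to
        scaling: fitted Y-hat equals the OLS fit."""
        x = rng.standard_normal(25)
        y = 2.0 * x + rng.normal(0, 0.1, 25)
        classes = np.where(y > np.median(y), "hi", "lo")
        X = _frame(x[:, None])
        model = mv.fit_plsda(X, classes, 1, cv_seed=0)
        Y = (classes[:, None] == np.array(model.classes)[None, :]).astype(float)
        Yc = Y - Y.mean(axis=0)
        xc = x - x.mean()
        ols = np.outer(xc, xc @ Yc / (xc @ xc))
        t = model.scores.iloc[:, 0].to_numpy()
        fitted = np.outer(t, model.y_loadings[:, 0])
        assert np.allclose(fitted, ols, atol=1e-8)

    def test_fold_count_reduced_for_tiny_n(self, rng):
        X = _frame(rng.standard_normal((5, 3)))
        model = mv.fit_plsda(X, ["A", "A", "B", "B", "A"], 1, cv_folds=7, cv_seed=0)
        assert model.cv_folds == 5


class TestOPLSDA:
    def test_reduces_to_pls_with_zero_orthogonal(self, rng):
        X = rng.standard_normal((30, 6))
        X[:15] += 1.0
        classes = ["A"] * 15 + ["B"] * 15
        op = mv.fit_oplsda(_frame(X), classes, n_components=1, cv_seed=0)
        pls = mv.fit_plsda(_frame(X), classes, 1, cv_seed=0)
        t_op = op.scores.iloc[:, 0].to_numpy()
        t_pls = pls.scores.iloc[:, 0].to_numpy()
        cos = abs(t_op @ t_pls) / (np.linalg.norm(t_op) * np.linalg.norm(t_pls))
        assert cos >= 1 - 1e-9

    def test_no_orthogonal_structure_degenerates(self, rng):
        y = np.array([1.0] * 10 + [0.0] * 10)
        v = rng.standard_normal(5)
        X = np.outer(y - y.mean(), v)  # purely predictive structure
        op = mv.fit_oplsda(_frame(X), ["A"] * 10 + ["B"] * 10, n_components=3, cv_seed=0)
        assert op.ortho_scores.shape[1] == 0 or np.allclose(
            op.ortho_scores.var().to_numpy(), 0.0, atol=1e-12
        )

    def test_r2x_partition_sums_to_total(self, rng):
        X = rng.standard_normal((40, 8))
        X[:20, :2] += 2.0
        X[:, 3] += 3 * rng.standard_normal(40)  # class-orthogonal variation
        op = mv.fit_oplsda(_frame(X), ["A"] * 20 + ["B"] * 20, n_components=3, cv_seed=0)
        assert op.r2x == pytest.approx(op.r2x_pred + sum(op.r2x_ortho), abs=1e-6)

    def test_predictive_orthogonal_scores_are_orthogonal(self, rng):
        X = rng.standard_normal((24, 6))
        X[:12, 0] += 2.0
        op = mv.fit_oplsda(_frame(X), ["A"] * 12 + ["B"] * 12, n_components=2, cv_seed=0)
        t, to = op.scores.iloc[:, 0].to_numpy(), op.ortho_scores.iloc[:, 0].to_numpy()
        assert abs(t @ to) <= 1e-6 * np.linalg.norm(t) * np.linalg.norm(to)

    def test_total_r2x_matches_projection_oracle(self, rng):
        """Modeled R2X equals the explained variance of the projection of
        the centred matrix onto the span of all score vectors."""
        X = rng.standard_normal((6, 4))
        op = mv.fit_oplsda(_frame(X), ["A", "B", "A", "B", "A", "B"], n_components=2, cv_seed=0)
        Xc = X - X.mean(axis=0)
        T = np.column_stack([op.scores.to_numpy(), op.ortho_scores.to_numpy()])
        proj = T @ np.linalg.lstsq(T, Xc, rcond=None)[0]
        assert op.r2x == pytest.approx((proj**2).sum() / (Xc**2).sum(), abs=1e-6)

    def test_three_classes_rejected(self, rng):
        X = _frame(rng.standard_normal((9, 3)))
        with pytest.raises(ValueError, match="fit_plsda"):
            mv.fit_oplsda(X, ["A", "B", "C"] * 3, 2)


class TestCvAnova:
    def test_press_equal_ssy_gives_one(self):
        assert mv.cv_anova(_stub_model(press=10.0, ssy=10.0)) == 1.0

    def test_p_monotone_in_press(self):
        ps = [mv.cv_anova(_stub_model(press=pr, ssy=10.0)) for pr in (8.0, 4.0, 1.0, 0.1)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert ps[-1] < 1e-6


class TestVipAndPcorr:
    def test_single_informative_variable(self, rng):
        X = rng.standard_normal((40, 12))
        y = np.array(["A"] * 20 + ["B"] * 20)
        X[:20, 0] += 3.0
        model = mv.fit_plsda(_frame(X), y, 2, cv_seed=0)
        assert model.vip.iloc[0] > 1.0
        assert float((model.vip**2).mean()) == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_columns_share_vip(self, rng):
        X = rng.standard_normal((30, 4))
        X[:15, 0] += 2.0
        X = np.column_stack([X, X[:, 0]])  # duplicate the informative column
        model = mv.fit_plsda(_frame(X), ["A"] * 15 + ["B"] * 15, 2, cv_seed=0)
        assert model.vip.iloc[0] == pytest.approx(model.vip.iloc[-1], abs=1e-9)

    def test_pcorr_of_score_itself_is_unit(self, rng):
        X = rng.standard_normal((30, 5))
        X[:15, 0] += 2.5
        model = mv.fit_plsda(_frame(X), ["A"] * 15 + ["B"] * 15, 1, cv_seed=0)
        t = model.scores.iloc[:, 0]
        Z = pd.DataFrame({"plus": t, "minus": -t, "const": 1.0}, index=t.index)
        pc = mv.p_corr(model, Z)
        assert pc["plus"] == pytest.approx(1.0)
        assert pc["minus"] == pytest.approx(-1.0)
        assert pc["const"] == 0.0


class TestVariableSelection:
    # reported (p(corr), VIP) pairs of the CRC-vs-CTRL discriminant model
    TABLE_PAIRS = [
        ("Standardized fecal Hb", 0.6948, 3.7443),
        ("CE (20:4)", 0.6846, 3.1189),
        ("CE (18:2)", 0.5408, 2.3798),
        ("CE (20:5)", 0.5250, 1.6608),
    ]

    def test_printed_pairs_pass_cutoffs_age_fails(self):
        names = [n for n, _, _ in self.TABLE_PAIRS] + ["Standardized age"]
        pcorr = pd.Series([p for _, p, _ in self.TABLE_PAIRS] + [0.438], index=names)
        vip = pd.Series([v for _, _, v in self.TABLE_PAIRS] + [2.024], index=names)
        sel = mv.select_variables(vip, pcorr)
        assert list(sel.index) == [n for n, _, _ in self.TABLE_PAIRS]  # VIP-descending
        assert "Standardized age" not in sel.index

    def test_empty_input_gives_empty_output(self):
        sel = mv.select_variables(pd.Series(dtype=float), pd.Series(dtype=float))
        assert sel.empty

    def test_negative_pcorr_passes_absolute_cutoff(self):
        sel = mv.select_variables(
            pd.Series({"a": 2.0, "b": 1.5}), pd.Series({"a": -0.6, "b": 0.2})
        )
        assert list(sel.index) == ["a"]


class TestClassificationList:
    def _model_with_predictions(self, preds):
        idx = pd.Index([f"s{i}" for i in range(len(preds))])
        m = _stub_model(press=1.0, ssy=2.0, n=len(preds))
        m.y_pred_cv = pd.DataFrame(
            {"POS": preds, "NEG": [1 - p for p in preds]}, index=idx
        )
        return m, pd.Series(["POS"] * len(preds), index=idx)

    def test_threshold_categories(self):
        model, truth = self._model_with_predictions([0.70, 0.50, 0.20, 0.62])
        table = mv.classification_list(model, truth).table
        pos = table[table["class_label"] == "POS"].set_index("sample_id")
        assert pos.loc["s0", "category"] == "BELONGS"
        assert pos.loc["s1", "category"] == "BORDERLINE" and not pos.loc["s1", "borderline_gt_06"]
        assert pos.loc["s2", "category"] == "NOT"
        assert pos.loc["s3", "category"] == "BORDERLINE" and pos.loc["s3", "borderline_gt_06"]

    def test_percentages_exclude_borderline(self):
        assert mv.classification_percentages(61, 7, 6) == pytest.approx(91.04, abs=0.005)
        assert mv.classification_percentages(25, 24, 7) == pytest.approx(78.12, abs=0.005)
        assert np.isnan(mv.classification_percentages(0, 5, 0))

    def test_counts_table_roundtrip(self):
        model, truth = self._model_with_predictions([0.9, 0.9, 0.1, 0.5])
        clist = mv.classification_list(model, truth)
        counts = mv.classification_percentage_table(clist, truth)
        assert counts.loc["POS", "BELONGS"] == 2
        assert counts.loc["POS", "NOT"] == 1
        assert counts.loc["POS", "pct_correct"] == pytest.approx(100 * 2 / 3)
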