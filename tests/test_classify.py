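"""Diagnostic layer: cut-off rule, logistic, trees, forests, CV, ROC."""

import numpy as np
import pandas as pd
import pytest

from cardiomad.classify import (CutoffEstimator, DiagnosticLogit,
                                DiagnosticLogitResults, GiniTreeClassifier,
                                LogitEstimator, ReferenceRange, TreeEstimator,
                                apply_cutoff_rule, cross_validate, fit_tree,
                                gini_impurity, reference_range_classify,
                                rf_importance, roc)
from cardiomad.phantom import generate_cohort_features
from cardiomad.segmentation import segment_level


class TestCutoffRule:
    def test_published_group_means_classified(self):
        assert apply_cutoff_rule({"madSD": 0.29, "maxT2": 80.5}) == "ACM"
        assert apply_cutoff_rule({"madSD": 0.22, "maxT2": 69.6}) == "HV"

    def test_strict_inequality_at_boundary(self):
        assert apply_cutoff_rule({"madSD": 0.22, "maxT2": 68.0}) == "HV"

    def test_and_versus_or_semantics(self):
        f = {"madSD": 0.20, "maxT2": 90.0}
        assert apply_cutoff_rule(f, combine="and") == "HV"
        assert apply_cutoff_rule(f, combine="or") == "ACM"

    def test_vectorised_over_dataframe(self):
        df = pd.DataFrame({"madSD": [0.1, 0.3], "maxT2": [60.0, 80.0]})
        assert apply_cutoff_rule(df).tolist() == ["HV", "ACM"]

    def test_missing_feature_rejected(self):
        with pytest.raises(KeyError):
            apply_cutoff_rule({"madSD": 0.3})


class TestLogistic:
    def test_published_odds_factors(self):
        res = DiagnosticLogitResults.from_coefficients(
            {"Intercept": -7.00, "maxT2": 0.03, "madSD": 20.34})
        assert round(res.odds_factor("madSD", 0.1), 2) == 7.64
        assert round(res.odds_factor("maxT2", 1.0), 2) == 1.03
        assert res.odds_factor("madSD", 0.0) == 1.0

    def test_unknown_feature_rejected(self):
        res = DiagnosticLogitResults.from_coefficients({"Intercept": 0.0, "x": 1.0})
        with pytest.raises(KeyError):
            res.odds_factor("y", 1.0)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        df = generate_cohort_features(150, 150, seed=0)
        X = df[["maxT2", "madSD"]].to_numpy()
        y = (df["label"] == "ACM").to_numpy(float)
        ours = DiagnosticLogit(X, y, feature_names=["maxT2", "madSD"]).fit()
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.allclose(ours.params.to_numpy(), ref.params, rtol=1e-5)
        assert np.allclose(ours.bse.to_numpy(), ref.bse, rtol=1e-4)

    def test_null_calibration(self):
        """With labels independent of X, |coef| < 3 SE nearly always."""
        rng = np.random.default_rng(0)
        ok = 0
        reps = 200
        for rep in range(reps):
            df = generate_cohort_features(500, 500, seed=6000 + rep)
            X = df[["maxT2", "madSD"]].to_numpy()
            y = rng.integers(0, 2, len(df)).astype(float)
            res = DiagnosticLogit(X, y).fit()
            ok += bool(np.all(np.abs(res.params.to_numpy()[1:])
                              < 3 * res.bse.to_numpy()[1:]))
        assert ok / reps >= 0.95

    def test_perfect_separation_flagged(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        y = np.array([0, 0, 0, 1, 1, 1.0])
        res = DiagnosticLogit(X, y).fit()
        assert res.separation and not res.converged

    def test_predict_and_summary(self):
        df = generate_cohort_features(100, 100, seed=1)
        res = DiagnosticLogit.from_dataframe(df, ["maxT2", "madSD"]).fit()
        p = res.predict(df[["maxT2", "madSD"]])
        assert np.all((p >= 0) & (p <= 1))
        assert "OR" in res.summary()
        ors = res.odds_ratios()
        assert np.all(ors.ci_lower <= ors.odds_ratio)
        assert np.all(ors.odds_ratio <= ors.ci_upper)

    def test_singular_design_rejected(self):
        X = np.column_stack([np.arange(10.0), np.arange(10.0)])
        y = (np.arange(10) % 2).astype(float)
        with pytest.raises(ValueError):
            DiagnosticLogit(X, y).fit()


class TestGiniTree:
    def test_gini_impurity_values(self):
        assert gini_impurity([2, 2]) == 0.5
        assert gini_impurity([4, 0]) == 0.0
        assert gini_impurity([3, 1]) == pytest.approx(0.375)
        with pytest.raises(ValueError):
            gini_impurity([0, 0])

    def test_midpoint_threshold_on_separable_values(self):
        X = np.array([[5.0]] * 5 + [[9.0]] * 5)
        y = np.array([0] * 5 + [1] * 5)
        tree = fit_tree(X, y, max_depth=1)
        assert tree.splits() == [(0, 7.0)]

    def test_pure_labels_give_single_leaf(self):
        tree = fit_tree(np.arange(10.0).reshape(-1, 1), np.zeros(10))
        assert tree.root.is_leaf

    def test_depth_one_equals_exhaustive_search_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.normal(0, 1, 40)
            y = (x + rng.normal(0, 1, 40) > 0).astype(int)
            if len(np.unique(y)) < 2:
                continue
            tree = fit_tree(x.reshape(-1, 1), y, max_depth=1, min_leaf=1)
            # brute force over all midpoints
            xs = np.sort(np.unique(x))
            best, best_thr = np.inf, None
            for thr in (xs[:-1] + xs[1:]) / 2:
                left, right = y[x <= thr], y[x > thr]
                g = (len(left) * gini_impurity(np.bincount(left, minlength=2))
                     + len(right) * gini_impurity(np.bincount(right, minlength=2))) / 40
                if g < best - 1e-12:
                    best, best_thr = g, thr
            assert tree.splits()[0][1] == pytest.approx(best_thr)

    def test_matches_sklearn_first_split(self):
        sk = pytest.importorskip("sklearn.tree")
        df = generate_cohort_features(200, 200, seed=5)
        X = df[["madSD", "maxT2"]].to_numpy()
        y = (df["label"] == "ACM").astype(int).to_numpy()
        ours = fit_tree(X, y, max_depth=1, min_leaf=5)
        ref = sk.DecisionTreeClassifier(max_depth=1, min_samples_leaf=5,
                                        criterion="gini").fit(X, y)
        f, thr = ours.splits()[0]
        assert f == ref.tree_.feature[0]
        assert thr == pytest.approx(ref.tree_.threshold[0], abs=1e-6)

    def test_predict_agrees_with_training_majority(self):
        df = generate_cohort_features(300, 300, seed=6)
        X = df[["madSD", "maxT2"]]
        y = df["label"].to_numpy()
        tree = fit_tree(X, y, max_depth=2)
        acc = (tree.predict(X) == y).mean()
        assert acc > 0.6
        d = tree.to_dict()
        assert set(d["classes"]) == {"ACM", "HV"}


class TestRandomForest:
    def test_null_feature_unimportant(self):
        rng = np.random.default_rng(0)
        n = 300
        x_signal = np.concatenate([rng.normal(0, 1, n), rng.normal(6, 1, n)])
        x_noise = rng.normal(0, 1, 2 * n)
        X = np.column_stack([x_signal, x_noise])
        y = np.array([0] * n + [1] * n)
        # mtry = p so every node sees the separating feature
        imp = rf_importance(X, y, n_trees=100, mtry=2, seed=1,
                            feature_names=["signal", "noise"])
        assert imp["noise"] < 0.1 * imp["signal"]

    def test_deterministic_for_fixed_seed(self):
        df = generate_cohort_features(60, 60, seed=2)
        X = df[["maxT2", "madSD"]]
        y = df["label"].to_numpy()
        a = rf_importance(X, y, n_trees=25, seed=9)
        b = rf_importance(X, y, n_trees=25, seed=9)
        pd.testing.assert_series_equal(a, b)

    def test_madsd_ranks_above_madt2(self):
        """Forest importance reproduces the madSD > madT2 ordering."""
        feats = ["globalT2", "globalSD", "maxT2", "maxSD", "madT2", "madSD"]
        wins = 0
        reps = 20
        for rep in range(reps):
            df = generate_cohort_features(250, 250, seed=7000 + rep)
            imp = rf_importance(df[feats], df["label"].to_numpy(),
                                n_trees=100, seed=rep)
            wins += bool(imp["madSD"] > imp["madT2"])
        assert wins / reps >= 0.9


class TestCrossValidation:
    def test_constant_classifier_on_balanced_data(self):
        class Always0:
            def fit(self, X, y):
                return self

            def predict(self, X):
                return np.zeros(len(X), dtype=int)

        X = np.arange(40.0).reshape(-1, 1)
        y = np.array([0, 1] * 20)
        res = cross_validate(Always0, X, y, k=10, seed=0)
        assert res.accuracy == 0.5

    def test_seed_determinism(self):
        df = generate_cohort_features(40, 40, seed=4)
        X = df[["maxT2", "madSD"]]
        y = df["label"].to_numpy()
        r1 = cross_validate(LogitEstimator, X, y, k=10, seed=3)
        r2 = cross_validate(LogitEstimator, X, y, k=10, seed=3)
        assert r1.accuracy == r2.accuracy

    def test_separable_cohort_scores_high(self):
        moments = {
            "HV": {"globalT2": (58.7, 4.2), "globalSD": (7.7, 1.9),
                   "maxT2": (69.6, 8.5), "maxSD": (12.5, 4.2),
                   "madT2": (0.07, 0.03), "madSD": (0.22, 0.05)},
            "ACM": {"globalT2": (68.9, 7.2), "globalSD": (10.1, 2.4),
                    "maxT2": (102.3, 16.8), "maxSD": (32.0, 8.6),
                    "madT2": (0.13, 0.02), "madSD": (0.43, 0.06)},
        }
        df = generate_cohort_features(200, 200, moments=moments, seed=8)
        res = cross_validate(LogitEstimator, df[["maxT2", "madSD"]],
                             df["label"].to_numpy(), k=10, seed=1)
        assert res.accuracy > 0.9

    def test_tree_and_cutoff_estimators_run(self):
        df = generate_cohort_features(50, 50, seed=9)
        y = df["label"].to_numpy()
        acc_tree = cross_validate(TreeEstimator, df[["madSD", "maxT2"]], y,
                                  k=5, seed=0).accuracy
        acc_cut = cross_validate(CutoffEstimator, df[["madSD", "maxT2"]], y,
                                 k=5, seed=0).accuracy
        assert 0.0 <= acc_tree <= 1.0 and 0.0 <= acc_cut <= 1.0


class TestROC:
    def test_perfect_and_uninformative_scores(self):
        assert roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], positive=1).auc == 1.0
        assert roc([5, 5, 5, 5], [0, 0, 1, 1], positive=1).auc == 0.5

    def test_hand_computed_pairwise_auc(self):
        assert roc([3, 1, 2, 4], [0, 0, 1, 1], positive=1).auc == 0.75

    def test_matches_sklearn(self):
        skm = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 200)
        s = rng.normal(y, 1.0)
        assert roc(s, y, positive=1).auc == pytest.approx(
            skm.roc_auc_score(y, s), abs=1e-12)

    def test_sensitivity_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 100)
        s = rng.normal(y, 1.0)
        res = roc(s, y, positive=1)
        assert np.all(np.diff(res.sensitivity) >= 0)  # thresholds descend

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc([1, 2, 3], [1, 1, 1], positive=1)


class TestReferenceRange:
    def _table(self, means):
        return pd.DataFrame({
            "mean_T2_ms": means,
            "level": [segment_level(s) for s in range(1, 17)],
        })

    def test_reference_means_are_negative(self):
        means = [56.7] * 6 + [58.1] * 6 + [62.2] * 4
        assert not reference_range_classify(self._table(means), k=2)
        assert not reference_range_classify(self._table(means), k=0.5)

    def test_threshold_arithmetic_at_k2_vs_k3(self):
        means = [65.0] + [56.7] * 5 + [58.1] * 6 + [62.2] * 4
        tab = self._table(means)
        assert reference_range_classify(tab, k=2)       # 65 > 56.7 + 8.2
        assert not reference_range_classify(tab, k=3)   # 65 < 56.7 + 12.3

    def test_k3_positives_subset_of_k2(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tab = self._table(rng.normal(60, 6, 16))
            if reference_range_classify(tab, k=3):
                assert reference_range_classify(tab, k=2)

    def test_unknown_level_rejected(self):
        tab = pd.DataFrame({"mean_T2_ms": [60.0], "level": ["outflow"]})
        with pytest.raises(ValueError):
            reference_range_classify(tab)

    def test_invalid_reference_rejected(self):
        with pytest.raises(ValueError):
            ReferenceRange(levels={"basal": (56.7, 0.0)})
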