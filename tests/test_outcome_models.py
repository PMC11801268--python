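"""SMOTE, CV random-forest classification, TreeSHAP, logistic threshold."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from alistrat._treeshap import forest_shap_values, tree_expected_value, tree_shap_values
from alistrat.outcome_models import (
    cv_rf_classify,
    fit_logistic_threshold,
    group_membership_models,
    shap_attribution,
    smote_oversample,
)


def two_gaussians(n, separation, seed=0, p=5):
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack(
        [rng.normal(0.0, 1.0, (half, p)), rng.normal(separation, 1.0, (n - half, p))]
    )
    y = np.array([0] * half + [1] * (n - half))
    idx = rng.permutation(n)
    return X[idx], y[idx]


class TestSmote:
    def test_balanced_input_identity(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.array([0] * 10 + [1] * 10)
        Xo, yo = smote_oversample(X, y, seed=0)
        np.testing.assert_array_equal(Xo, X)
        np.testing.assert_array_equal(yo, y)

    def test_synthetic_points_on_segment(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]] + [[10.0, 10.0]] * 10)
        y = np.array([1, 1] + [0] * 10)
        Xo, yo = smote_oversample(X, y, seed=3)
        synth = Xo[len(X):]
        # Points interpolated between (0,0) and (1,1): x == y in [0, 1].
        np.testing.assert_allclose(synth[:, 0], synth[:, 1], atol=1e-12)
        assert np.all(synth >= -1e-12) and np.all(synth <= 1 + 1e-12)

    def test_counts_balance(self, rng):
        X = rng.normal(size=(100, 4))
        y = np.array([1] * 10 + [0] * 90)
        Xo, yo = smote_oversample(X, y, seed=1)
        assert (yo == 1).sum() == (yo == 0).sum() == 90
        assert len(Xo) == 180  # 80 synthetic rows appended
        np.testing.assert_array_equal(Xo[:100], X)  # originals preserved

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            smote_oversample(rng.normal(size=(5, 2)), np.zeros(5))


class TestCvRfClassify:
    def test_separable_data_high_auc(self):
        X, y = two_gaussians(200, separation=6.0, seed=0)
        rep = cv_rf_classify(X, y, seed=0, n_trees=100)
        assert rep.auc_mean >= 0.99
        assert len(rep.per_fold_auc) == 5
        assert rep.auc_sd >= 0.0

    def test_permuted_labels_chance_level(self, rng):
        X, y = two_gaussians(300, separation=6.0, seed=1)
        y_perm = rng.permutation(y)
        rep = cv_rf_classify(X, y_perm, seed=1, n_trees=50)
        assert 0.35 <= rep.auc_mean <= 0.65

    def test_mean_roc_monotone(self):
        X, y = two_gaussians(150, separation=2.0, seed=2)
        rep = cv_rf_classify(X, y, seed=2, n_trees=50)
        fpr, tpr = rep.mean_roc
        assert np.all(np.diff(tpr) >= -1e-12)
        assert tpr[0] == 0.0 and tpr[-1] == 1.0

    def test_minority_smaller_than_folds_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.array([1] * 3 + [0] * 17)
        with pytest.raises(ValueError):
            cv_rf_classify(X, y, n_folds=5)


class TestTreeShap:
    def test_local_accuracy_forest(self, rng):
        X = rng.normal(size=(120, 6))
        y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(int)
        rf = RandomForestClassifier(n_estimators=30, random_state=0).fit(X, y)
        phi, base = forest_shap_values(rf, X[:40])
        np.testing.assert_allclose(base + phi.sum(axis=1), rf.predict_proba(X[:40])[:, 1], atol=1e-9)

    def test_dummy_feature_zero_attribution(self, rng):
        X = rng.normal(size=(150, 4))
        X[:, 3] = 7.0  # constant: never split on
        y = (X[:, 0] > 0).astype(int)
        rf = RandomForestClassifier(n_estimators=20, random_state=0).fit(X, y)
        phi, _ = forest_shap_values(rf, X[:30])
        np.testing.assert_array_equal(phi[:, 3], 0.0)

    def test_single_stump_attribution(self, rng):
        X = rng.normal(size=(100, 3))
        y = (X[:, 1] > 0).astype(int)
        stump = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        phi = tree_shap_values(stump.tree_, X[:20])
        base = tree_expected_value(stump.tree_)
        pred = stump.predict_proba(X[:20])[:, 1]
        np.testing.assert_allclose(phi[:, 1], pred - base, atol=1e-12)
        np.testing.assert_array_equal(phi[:, 0], 0.0)
        np.testing.assert_array_equal(phi[:, 2], 0.0)

    def test_shap_attribution_wrapper_and_mismatch(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 3)), columns=["a", "b", "c"])
        y = (X["a"] > 0).astype(int)
        rep = cv_rf_classify(X, y, seed=0, n_trees=20)
        sm = shap_attribution(rep.model_ref, X)
        assert np.abs(sm.base_value + sm.values.sum(axis=1) - sm.scores).max() < 1e-9
        assert sm.mean_abs().index[0] == "a"
        with pytest.raises(ValueError):
            shap_attribution(rep.model_ref, X[["a", "b"]])

    def test_outcome_driver_dominates_shap(self, default_cohort):
        # The outcome is a logistic in day-7 PT%, and admission PT%/equilibrium
        # correlates (Alb) carry the signal: a PT-linked feature must rank top.
        from alistrat.preprocess import cohort_to_admission_table, encode_categoricals

        X = encode_categoricals(cohort_to_admission_table(default_cohort)).data
        y = np.array([p.outcome == "non-TFS" for p in default_cohort.patients]).astype(int)
        rep = cv_rf_classify(X, y, seed=0, n_trees=100)
        sm = shap_attribution(rep.model_ref, X.iloc[:80], feature_names=list(X.columns))
        top = set(sm.mean_abs().head(3).index)
        assert top & {"PT_day0", "Alb", "Plt", "liver_atrophy"}


class TestLogisticThreshold:
    def test_symmetric_threshold(self):
        pt = np.array([40.0] * 30 + [60.0] * 30)
        y = ["non-TFS"] * 30 + ["TFS"] * 30
        thr = fit_logistic_threshold(pt, y, with_cv=False)
        assert thr.threshold == pytest.approx(50.0, abs=0.5)
        assert thr.slope < 0

    def test_recovery_on_generated_cohorts(self):
        from alistrat.synthetic_cohort import CohortConfig, generate_cohort

        recovered = []
        for seed in range(5):
            c = generate_cohort(CohortConfig(n=300, seed=100 + seed))
            pt7 = np.array([p.pt_at(7) for p in c.patients])
            thr = fit_logistic_threshold(pt7, [p.outcome for p in c.patients], with_cv=False)
            recovered.append(thr.threshold)
        assert all(46.0 <= t <= 54.0 for t in recovered)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic_threshold([40.0, 50.0], ["TFS", "TFS"])


class TestGroupMembership:
    def test_separable_admission_features(self, rng):
        n = 120
        groups = np.array(["G3", "G4", "G5", "G6"])[rng.integers(0, 4, n)]
        X = pd.get_dummies(pd.Series(groups)).to_numpy(float)
        X = X + rng.normal(0, 0.01, X.shape)
        reps = group_membership_models(X, groups, seed=0, n_trees=50)
        assert set(reps) == {"G3", "G4", "G5", "G6"}
        assert all(r.auc_mean >= 0.95 for r in reps.values())

    def test_absent_group_skipped(self, rng):
        groups = np.array(["G3"] * 30 + ["G4"] * 30)
        X = rng.normal(size=(60, 3))
        reps = group_membership_models(X, groups, seed=0, n_trees=20)
        assert "G5" not in reps and "G6" not in reps
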