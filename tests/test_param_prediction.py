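"""Leave-one-out RF parameter prediction, per-tree intervals, tier metrics."""

import numpy as np
import pandas as pd
import pytest

from alistrat.param_prediction import (
    ParamForecast,
    TierEvaluation,
    evaluate_tiers,
    forecast_trajectory,
    loo_rf_predict_params,
    rmse_reduction_fraction,
)
from alistrat.pt_model import PTParams


def make_targets(rng, n):
    return pd.DataFrame(
        {
            "g": rng.uniform(20, 90, n),
            "D": rng.uniform(0.3, 1.5, n),
            "P0": rng.uniform(20, 80, n),
        },
        index=pd.Index([f"P{i:03d}" for i in range(n)], name="id"),
    )


class TestLooRfPredict:
    def test_perfectly_encoding_features(self, rng):
        targets = make_targets(rng, 120)
        features = targets.copy()  # targets leak directly into features
        fcs = loo_rf_predict_params(features, targets, n_trees=60, seed=0)
        pred = np.array([f.predicted.as_array() for f in fcs])
        rel = np.abs(pred - targets.to_numpy()) / targets.to_numpy()
        assert np.median(rel) < 0.10

    def test_constant_targets(self, rng):
        n = 20
        targets = pd.DataFrame(
            {"g": [40.0] * n, "D": [0.8] * n, "P0": [30.0] * n},
            index=pd.Index([f"P{i}" for i in range(n)], name="id"),
        )
        features = pd.DataFrame(
            rng.normal(size=(n, 3)), index=targets.index, columns=["a", "b", "c"]
        )
        fcs = loo_rf_predict_params(features, targets, n_trees=25, seed=0)
        for fc in fcs:
            np.testing.assert_allclose(fc.predicted.as_array(), [40.0, 0.8, 30.0])
            assert np.allclose(fc.per_tree, fc.per_tree[0])

    def test_uninformative_features_near_zero_r2(self, rng):
        targets = make_targets(rng, 150)
        features = pd.DataFrame(
            rng.normal(size=(150, 4)), index=targets.index, columns=list("abcd")
        )
        fcs = loo_rf_predict_params(features, targets, n_trees=50, seed=0)
        pred = np.array([f.predicted.as_array()[0] for f in fcs])
        truth = targets["g"].to_numpy()
        ss_res = np.sum((truth - pred) ** 2)
        ss_tot = np.sum((truth - truth.mean()) ** 2)
        assert 1 - ss_res / ss_tot < 0.15

    def test_duplicate_ids_rejected(self, rng):
        targets = make_targets(rng, 5)
        features = targets.copy()
        features.index = pd.Index(["a", "a", "b", "c", "d"], name="id")
        targets.index = features.index
        with pytest.raises(ValueError):
            loo_rf_predict_params(features, targets)


class TestForecastTrajectory:
    def make_forecast(self, per_tree):
        per_tree = np.asarray(per_tree, dtype=float)
        mean = per_tree.mean(axis=0)
        return ParamForecast(
            id="x", predicted=PTParams(*mean), per_tree=per_tree
        )

    def test_identical_trees_collapse_interval(self):
        fc = forecast_trajectory(self.make_forecast([[50, 1, 20]] * 7))
        np.testing.assert_allclose(fc.trajectory_lo, fc.trajectory_mean)
        np.testing.assert_allclose(fc.trajectory_hi, fc.trajectory_mean)

    def test_percentiles_linear_interpolation(self):
        # Two trees differing only in P0 (20 vs 40): at t=0 the type-7
        # percentiles of {20, 40} are 20.5 and 39.5.
        fc = forecast_trajectory(self.make_forecast([[50, 1, 20], [50, 1, 40]]))
        assert fc.trajectory_lo[0] == pytest.approx(20.5)
        assert fc.trajectory_hi[0] == pytest.approx(39.5)

    def test_inflating_spread_never_narrows_interval(self, rng):
        base = np.array([[50.0, 1.0, 30.0]]) + rng.normal(0, 1, (40, 3)) * [2, 0.05, 2]
        fc1 = forecast_trajectory(self.make_forecast(base))
        mean = base.mean(axis=0)
        inflated = mean + (base - mean) * 2.0
        fc2 = forecast_trajectory(self.make_forecast(inflated))
        assert np.all(fc2.trajectory_lo <= fc1.trajectory_lo + 1e-9)
        assert np.all(fc2.trajectory_hi >= fc1.trajectory_hi - 1e-9)

    def test_mean_within_per_tree_envelope(self, rng):
        per_tree = np.abs(rng.normal([50, 1, 30], [5, 0.1, 3], size=(30, 3)))
        fc = forecast_trajectory(self.make_forecast(per_tree))
        assert np.all(fc.trajectory_lo <= fc.trajectory_mean + 1e-9)
        assert np.all(fc.trajectory_mean <= fc.trajectory_hi + 1e-9)


class TestEvaluation:
    def _eval(self, tier, rmse):
        return TierEvaluation(
            tier=tier, rmse_per_patient=np.array([rmse]), rmse_mean=rmse, r2_fit_vs_pred=0.9
        )

    def test_reduction_fraction_arithmetic(self):
        evals = [self._eval("D0", 10.0), self._eval("D2", 4.0), self._eval("D7", 2.0)]
        assert rmse_reduction_fraction(evals) == pytest.approx(0.75)

    def test_reduction_boundaries(self):
        assert rmse_reduction_fraction(
            [self._eval("D0", 10.0), self._eval("D2", 10.0), self._eval("D7", 2.0)]
        ) == pytest.approx(0.0)
        assert rmse_reduction_fraction(
            [self._eval("D0", 10.0), self._eval("D2", 2.0), self._eval("D7", 2.0)]
        ) == pytest.approx(1.0)

    def test_missing_tier_and_zero_denominator(self):
        with pytest.raises(ValueError):
            rmse_reduction_fraction([self._eval("D0", 10.0), self._eval("D2", 5.0)])
        with pytest.raises(ValueError):
            rmse_reduction_fraction(
                [self._eval("D0", 2.0), self._eval("D2", 2.0), self._eval("D7", 2.0)]
            )

    def test_perfect_forecast_metrics(self):
        from alistrat.synthetic_cohort import CohortConfig, generate_cohort

        cohort = generate_cohort(CohortConfig(n=8, seed=0, noise_sd=0.0))
        fitted = {p.id: p.true_params for p in cohort.patients}
        fcs = []
        for p in cohort.patients:
            fc = ParamForecast(
                id=p.id,
                predicted=p.true_params,
                per_tree=np.tile(p.true_params.as_array(), (5, 1)),
            )
            fcs.append(forecast_trajectory(fc))
        evals = evaluate_tiers(cohort, {"D0": fcs}, fitted)
        assert evals[0].rmse_mean == pytest.approx(0.0, abs=1e-9)
        assert evals[0].r2_fit_vs_pred == pytest.approx(1.0)

    def test_constant_prediction_negative_r2_allowed(self):
        from alistrat.synthetic_cohort import CohortConfig, generate_cohort

        cohort = generate_cohort(CohortConfig(n=8, seed=1, noise_sd=0.0))
        fitted = {p.id: p.true_params for p in cohort.patients}
        const = PTParams(40.0, 0.8, 50.0)
        fcs = [
            forecast_trajectory(
                ParamForecast(id=p.id, predicted=const, per_tree=np.tile(const.as_array(), (5, 1)))
            )
            for p in cohort.patients
        ]
        evals = evaluate_tiers(cohort, {"D0": fcs}, fitted)
        assert evals[0].r2_fit_vs_pred <= 1.0  # may be negative by definition
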