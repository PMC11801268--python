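"""Leave-one-out random-forest prediction of individual PT% trajectories.

Tiered clinical features (admission data, optionally extended with
day-stamped blood values and treatment flags) are regressed onto the
per-patient kinetic parameters (g, D, P0) estimated by the mixed-effects
fit.  Each held-out patient's forest is trained on all other patients;
multi-output trees predict a coherent (g, D, P0) triple per tree, so the
95% prediction interval of the PT% trajectory is read off the per-tree
closed-form trajectories (pointwise 2.5th/97.5th percentiles, linear
interpolation).  Tier quality is summarized by per-patient RMSE against the
observed PT% and the pooled determination coefficient between fitted and
predicted trajectories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from alistrat.pt_model import PTParams, simulate_trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "ParamForecast",
    "TierEvaluation",
    "loo_rf_predict_params",
    "forecast_trajectory",
    "evaluate_tiers",
    "rmse_reduction_fraction",
]

DAY_GRID = (0.0, 1.0, 2.0, 3.0, 7.0)


@dataclass
class ParamForecast:
    id: str
    predicted: PTParams
    per_tree: np.ndarray  # (n_trees, 3) parameter triples
    trajectory_mean: np.ndarray | None = None
    trajectory_lo: np.ndarray | None = None
    trajectory_hi: np.ndarray | None = None
    times: np.ndarray | None = None


@dataclass
class TierEvaluation:
    tier: str
    rmse_per_patient: np.ndarray
    rmse_mean: float
    r2_fit_vs_pred: float
    r2_per_day: dict[float, float] = field(default_factory=dict)
    coverage: float | None = None


def loo_rf_predict_params(
    features: pd.DataFrame,
    targets: pd.DataFrame,
    n_trees: int = 500,
    seed: int = 0,
) -> list[ParamForecast]:
    """Leave-one-out multi-output RF regression of (g, D, P0).

    ``features`` and ``targets`` are aligned on patient id (index);
    ``targets`` has columns g, D, P0 on the natural scale.  Tree predictions
    are averages of positive training values and hence positive.
    """
    if features.index.duplicated().any():
        raise ValueError("duplicate patient ids in features")
    ids = list(features.index)
    if len(ids) < 3:
        raise ValueError("need at least 3 patients for leave-one-out prediction")
    targets = targets.loc[ids, ["g", "D", "P0"]]
    X = features.to_numpy(dtype=float)
    Y = targets.to_numpy(dtype=float)
    n = len(ids)
    forecasts = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        rf = RandomForestRegressor(
            n_estimators=n_trees, max_features=1.0, random_state=seed, n_jobs=1
        )
        rf.fit(X[mask], Y[mask])
        per_tree = np.vstack([est.predict(X[i : i + 1])[0] for est in rf.estimators_])
        mean = per_tree.mean(axis=0)
        forecasts.append(
            ParamForecast(
                id=str(ids[i]),
                predicted=PTParams(g=float(mean[0]), D=float(mean[1]), P0=float(mean[2])),
                per_tree=per_tree,
            )
        )
    return forecasts


def forecast_trajectory(forecast: ParamForecast, times=DAY_GRID) -> ParamForecast:
    """Attach the trajectory mean and 95% per-tree prediction interval.

    The mean trajectory uses the ensemble-mean parameters; the bounds are
    the pointwise 2.5/97.5 percentiles (linear interpolation) over the
    per-tree closed-form trajectories.
    """
    if forecast.per_tree.size == 0:
        raise ValueError("per_tree parameter sets are required")
    times = np.asarray(times, dtype=float)
    tree_traj = np.vstack(
        [
            simulate_trajectory(PTParams(g=row[0], D=row[1], P0=row[2]), times)
            for row in forecast.per_tree
        ]
    )
    forecast.times = times
    forecast.trajectory_mean = simulate_trajectory(forecast.predicted, times)
    forecast.trajectory_lo = np.percentile(tree_traj, 2.5, axis=0)
    forecast.trajectory_hi = np.percentile(tree_traj, 97.5, axis=0)
    return forecast


def _r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)


def evaluate_tiers(
    cohort,
    forecasts_per_tier: dict[str, list[ParamForecast]],
    fitted_params: dict[str, PTParams],
    day_grid=DAY_GRID,
) -> list[TierEvaluation]:
    """Per-tier RMSE against observed PT% and R² of fitted vs. predicted.

    RMSE is per patient over the day grid (missing observed days skipped);
    the determination coefficient pools the mixed-effects fitted values and
    the RF-predicted values across all patients and days, with the per-day
    breakdown also reported.  Coverage is the fraction of patient-days whose
    observed PT% lies inside the 95% per-tree interval.
    """
    day_grid = np.asarray(day_grid, dtype=float)
    obs = {p.id: np.array([p.pt_at(d) for d in day_grid]) for p in cohort.patients}
    evals = []
    for tier, forecasts in forecasts_per_tier.items():
        rmses, ids_used = [], []
        pooled_fit, pooled_pred, pooled_day = [], [], []
        n_cov = n_tot = 0
        for fc in forecasts:
            if fc.id not in obs or fc.id not in fitted_params:
                logger.warning("tier %s: no observations/fit for %s; excluded", tier, fc.id)
                continue
            if fc.trajectory_mean is None or not np.array_equal(fc.times, day_grid):
                forecast_trajectory(fc, day_grid)
            y = obs[fc.id]
            ok = np.isfinite(y)
            rmses.append(float(np.sqrt(np.mean((y[ok] - fc.trajectory_mean[ok]) ** 2))))
            ids_used.append(fc.id)
            fit_traj = simulate_trajectory(fitted_params[fc.id], day_grid)
            pooled_fit.append(fit_traj)
            pooled_pred.append(fc.trajectory_mean)
            pooled_day.append(day_grid)
            inside = (y[ok] >= fc.trajectory_lo[ok]) & (y[ok] <= fc.trajectory_hi[ok])
            n_cov += int(inside.sum())
            n_tot += int(ok.sum())
        pooled_fit = np.concatenate(pooled_fit)
        pooled_pred = np.concatenate(pooled_pred)
        pooled_day = np.concatenate(pooled_day)
        r2_per_day = {
            float(d): _r2(pooled_fit[pooled_day == d], pooled_pred[pooled_day == d])
            for d in day_grid
        }
        evals.append(
            TierEvaluation(
                tier=tier,
                rmse_per_patient=np.asarray(rmses),
                rmse_mean=float(np.mean(rmses)),
                r2_fit_vs_pred=_r2(pooled_fit, pooled_pred),
                r2_per_day=r2_per_day,
                coverage=n_cov / n_tot if n_tot else None,
            )
        )
    return evals


def rmse_reduction_fraction(evals: list[TierEvaluation]) -> float:
    """Fraction of the admission-to-day-7 RMSE improvement reached by day 2.

    ``(RMSE(D0) - RMSE(D2)) / (RMSE(D0) - RMSE(D7))``; an error is raised if
    a tier is missing and a flagged ValueError if the denominator is not
    positive (no improvement from admission to day 7).
    """
    by_tier = {e.tier: e.rmse_mean for e in evals}
    for t in ("D0", "D2", "D7"):
        if t not in by_tier:
            raise ValueError(f"tier {t} missing from evaluations")
    denom = by_tier["D0"] - by_tier["D7"]
    if denom <= 0:
        raise ValueError("no RMSE improvement from D0 to D7; reduction fraction undefined")
    return (by_tier["D0"] - by_tier["D2"]) / denom
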