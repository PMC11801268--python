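"""End-to-end pipeline: synthesize/load -> preprocess -> NLMEM -> cluster ->
classify -> predict trajectories -> evaluate.

Each stage reads only prior-stage artifacts; a single global seed is fanned
out to per-stage seeds through a counter-based scheme, and every output file
is listed in the run manifest with a checksum so that reruns with the same
config and seed are byte-reproducible for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from alistrat import __version__
from alistrat.io import load_deposited, write_cohort
from alistrat.nlmem import SaemConfig, estimate_all_eb, fit_population_saem
from alistrat.outcome_models import (
    cv_rf_classify,
    fit_logistic_threshold,
    group_membership_models,
    shap_attribution,
)
from alistrat.param_prediction import (
    evaluate_tiers,
    forecast_trajectory,
    loo_rf_predict_params,
    rmse_reduction_fraction,
)
from alistrat.preprocess import (
    build_tier,
    cohort_to_admission_table,
    encode_categoricals,
    filter_variables,
    impute_chained,
)
from alistrat.synthetic_cohort import CohortConfig, generate_cohort
from alistrat.trajectory_clustering import cluster_trajectories, elbow_curve, relabel_groups

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

STAGES = ("synth", "preprocess", "fit_nlmem", "cluster", "classify", "predict", "evaluate")


@dataclass
class PipelineConfig:
    n: int = 150
    seed: int = 0
    noise_sd: float = 3.0
    outcome_crossing: float = 50.0
    outcome_steepness: float = 0.3
    k_clusters: int = 6
    cluster_n_init: int = 5
    saem_explore: int = 300
    saem_smooth: int = 200
    n_trees: int = 200
    tiers: tuple = ("D0", "DTI0", "D1", "D2", "D3", "D7")
    shap_max_samples: int = 100
    imputations: int = 1
    missing_rates: dict = field(default_factory=dict)
    cohort_path: str | None = None  # load instead of synthesize

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config key(s): {sorted(bad)}")
        if "tiers" in raw:
            raw["tiers"] = tuple(raw["tiers"])
        return cls(**raw)


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict[str, int]
    timings: dict[str, float]
    artifacts: dict[str, dict]
    version: str = __version__

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))


def _stage_seed(global_seed: int, stage: str) -> int:
    # Counter-based fan-out; stable across runs and insertion order.
    return int(np.random.SeedSequence([global_seed, STAGES.index(stage)]).generate_state(1)[0] % (2**31))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig | str | Path, outdir) -> RunManifest:
    """Run all stages; artifacts under ``outdir``; returns the manifest."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {s: _stage_seed(config.seed, s) for s in STAGES}
    timings: dict[str, float] = {}
    artifacts: dict[str, dict] = {}

    def record(name: str, path: Path) -> None:
        artifacts[name] = {"path": str(path), "sha256": _checksum(path)}

    # --- synth / load ---
    t0 = time.time()
    if config.cohort_path:
        cohort = load_deposited(config.cohort_path)
    else:
        cohort = generate_cohort(
            CohortConfig(
                n=config.n,
                seed=seeds["synth"],
                noise_sd=config.noise_sd,
                outcome_crossing=config.outcome_crossing,
                outcome_steepness=config.outcome_steepness,
            )
        )
        if config.missing_rates:
            from alistrat.synthetic_cohort import inject_missingness

            cohort = inject_missingness(cohort, config.missing_rates, seed=seeds["synth"])
    paths = write_cohort(cohort, outdir / "cohort", seed=seeds["synth"])
    for k, p in paths.items():
        record(f"cohort_{k}", p)
    timings["synth"] = time.time() - t0

    # --- preprocess ---
    t0 = time.time()
    kept = filter_variables(cohort, max_missing=0.20)
    adm = cohort_to_admission_table(cohort)[kept]
    encoded = encode_categoricals(adm)
    imputed = impute_chained(encoded, m=config.imputations, seed=seeds["preprocess"])[0]
    imputed.data.to_csv(outdir / "admission_imputed.csv")
    record("admission_imputed", outdir / "admission_imputed.csv")
    timings["preprocess"] = time.time() - t0

    # --- NLMEM fit ---
    t0 = time.time()
    pop = fit_population_saem(
        cohort,
        SaemConfig(n_explore=config.saem_explore, n_smooth=config.saem_smooth, seed=seeds["fit_nlmem"]),
    )
    ebs = estimate_all_eb(pop, cohort)
    params_df = pd.DataFrame(
        [
            {"id": e.id, "g": e.params.g, "D": e.params.D, "P0": e.params.P0,
             "eta_g": e.eta[0], "eta_D": e.eta[1], "eta_P0": e.eta[2]}
            for e in ebs
        ]
    ).set_index("id")
    params_df.to_csv(outdir / "individual_params.csv")
    record("individual_params", outdir / "individual_params.csv")
    (outdir / "population_model.json").write_text(
        json.dumps(
            {"theta": {"g": pop.theta.g, "D": pop.theta.D, "P0": pop.theta.P0},
             "omega": pop.omega.tolist(), "sigma": pop.sigma},
            indent=1,
        )
    )
    record("population_model", outdir / "population_model.json")
    timings["fit_nlmem"] = time.time() - t0

    # --- clustering ---
    t0 = time.time()
    X = cohort.pt_matrix()
    complete = np.all(np.isfinite(X), axis=1)
    res = relabel_groups(
        cluster_trajectories(X[complete], config.k_clusters, n_init=config.cluster_n_init,
                             seed=seeds["cluster"])
    )
    names = res.named_labels()
    ids = [p.id for p, c in zip(cohort.patients, complete) if c]
    labels_df = pd.DataFrame({"id": ids, "group": names}).set_index("id")
    labels_df.to_csv(outdir / "cluster_labels.csv")
    record("cluster_labels", outdir / "cluster_labels.csv")
    cent = pd.DataFrame(res.centroids, index=res.group_names, columns=[0, 1, 2, 3, 7])
    cent.to_csv(outdir / "cluster_centroids.csv")
    record("cluster_centroids", outdir / "cluster_centroids.csv")
    elbow = elbow_curve(X[complete], range(2, min(9, complete.sum())), seed=seeds["cluster"], n_init=2)
    pd.DataFrame(elbow, columns=["k", "inertia"]).to_csv(outdir / "elbow.csv", index=False)
    record("elbow", outdir / "elbow.csv")
    timings["cluster"] = time.time() - t0

    # --- classifiers & threshold ---
    t0 = time.time()
    y_outcome = np.array([1 if p.outcome == "non-TFS" else 0 for p in cohort.patients])
    Xfeat = imputed.data
    rep = cv_rf_classify(Xfeat, y_outcome, seed=seeds["classify"], n_trees=config.n_trees)
    shap_n = min(config.shap_max_samples, len(Xfeat))
    shap = shap_attribution(rep.model_ref, Xfeat.iloc[:shap_n], feature_names=list(Xfeat.columns))
    summary = {
        "outcome_auc_mean": rep.auc_mean,
        "outcome_auc_sd": rep.auc_sd,
        "outcome_fold_aucs": rep.per_fold_auc,
        "top_shap_features": shap.mean_abs().head(10).to_dict(),
    }
    pd.DataFrame(shap.values, columns=shap.feature_names).to_csv(outdir / "shap_outcome.csv", index=False)
    record("shap_outcome", outdir / "shap_outcome.csv")

    day7 = np.array([p.pt_at(7) for p in cohort.patients])
    ok7 = np.isfinite(day7)
    thr = fit_logistic_threshold(day7[ok7], y_outcome[ok7], seed=seeds["classify"])
    summary["pt_threshold"] = thr.threshold
    summary["threshold_cv_auc"] = thr.cv_auc_mean

    group_by_id = labels_df["group"].to_dict()
    glabels = np.array([group_by_id.get(p.id, "NA") for p in cohort.patients])
    greps = group_membership_models(
        Xfeat, glabels, seed=seeds["classify"], n_trees=config.n_trees
    )
    summary["group_auc"] = {g: r.auc_mean for g, r in greps.items()}
    timings["classify"] = time.time() - t0

    # --- trajectory prediction per tier ---
    t0 = time.time()
    targets = params_df[["g", "D", "P0"]]
    common = [pid for pid in Xfeat.index if pid in targets.index]
    forecasts_per_tier = {}
    rows = []
    for tier in config.tiers:
        tier_table = build_tier(cohort, imputed, tier)
        feats = tier_table.data.loc[common].fillna(tier_table.data.mean(numeric_only=True))
        fcs = loo_rf_predict_params(feats, targets.loc[common], n_trees=config.n_trees,
                                    seed=seeds["predict"])
        for fc in fcs:
            forecast_trajectory(fc)
            for d, m, lo, hi in zip(fc.times, fc.trajectory_mean, fc.trajectory_lo, fc.trajectory_hi):
                rows.append((tier, fc.id, d, m, lo, hi))
        forecasts_per_tier[tier] = fcs
    pd.DataFrame(rows, columns=["tier", "id", "day", "mean", "lo", "hi"]).to_csv(
        outdir / "forecasts.csv", index=False
    )
    record("forecasts", outdir / "forecasts.csv")
    timings["predict"] = time.time() - t0

    # --- evaluation ---
    t0 = time.time()
    from alistrat.pt_model import PTParams

    fitted = {pid: PTParams(g=row["g"], D=row["D"], P0=row["P0"]) for pid, row in params_df.iterrows()}
    evals = evaluate_tiers(cohort, forecasts_per_tier, fitted)
    eval_df = pd.DataFrame(
        [
            {"tier": e.tier, "rmse_mean": e.rmse_mean, "r2_fit_vs_pred": e.r2_fit_vs_pred,
             "coverage": e.coverage}
            for e in evals
        ]
    )
    eval_df.to_csv(outdir / "tier_evaluation.csv", index=False)
    record("tier_evaluation", outdir / "tier_evaluation.csv")
    try:
        summary["rmse_reduction_fraction"] = rmse_reduction_fraction(evals)
    except ValueError:
        summary["rmse_reduction_fraction"] = None
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    record("summary", outdir / "summary.json")
    timings["evaluate"] = time.time() - t0

    cfg_hash = hashlib.sha256(json.dumps(asdict(config), sort_keys=True, default=str).encode()).hexdigest()[:16]
    manifest = RunManifest(config_hash=cfg_hash, seeds=seeds, timings=timings, artifacts=artifacts)
    manifest.save(outdir / "manifest.json")
    return manifest
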