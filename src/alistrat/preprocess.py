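"""Data preparation: missingness filtering, dummy coding, chained-equation
multiple imputation, and assembly of the tiered feature datasets.

Tier naming convention (used for the trajectory-prediction experiments):
``D0`` is the admission dataset (blood tests and demographics at day 0),
``Dt`` adds day-stamped blood values through day t postadmission, and
``DTIt`` further adds the intensive-care treatment flags through day t.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from alistrat.synthetic_cohort import Cohort, TREATMENT_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "TierSpec",
    "cohort_to_admission_table",
    "filter_variables",
    "encode_categoricals",
    "impute_chained",
    "build_tier",
    "TIER_ORDER",
]

TIER_ORDER = ("D0", "DTI0", "D1", "DTI1", "D2", "DTI2", "D3", "DTI3", "D7", "DTI7")


@dataclass
class FeatureTable:
    """Fully numeric per-patient feature matrix (rows indexed by patient id)."""

    data: pd.DataFrame
    tier: str | None = None
    categorical_levels: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValueError("column names must be unique")


@dataclass(frozen=True)
class TierSpec:
    tier: str
    includes_treatment: bool
    max_day: int

    @classmethod
    def parse(cls, name: str) -> "TierSpec":
        m = re.fullmatch(r"(D|DTI)(\d+)", name)
        if not m or name not in TIER_ORDER:
            raise ValueError(f"unknown tier name: {name!r} (expected one of {TIER_ORDER})")
        return cls(tier=name, includes_treatment=m.group(1) == "DTI", max_day=int(m.group(2)))


def cohort_to_admission_table(cohort: Cohort) -> pd.DataFrame:
    """Wide admission-feature table (raw, categoricals as strings)."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    df = pd.DataFrame(
        [dict(p.features_admission) for p in cohort.patients],
        index=pd.Index([p.id for p in cohort.patients], name="id"),
    )
    return df


def filter_variables(cohort: Cohort, max_missing: float = 0.20) -> list[str]:
    """Admission variables whose realized missing fraction is <= ``max_missing``.

    A variable missing in strictly more than ``max_missing`` of patients is
    excluded.  Returns the retained variable names (order preserved).
    """
    if not 0 < max_missing <= 1:
        raise ValueError("max_missing must be in (0, 1]")
    df = cohort_to_admission_table(cohort)
    frac = df.isna().mean()
    kept = [c for c in df.columns if frac[c] <= max_missing]
    if not kept:
        logger.warning("all variables exceed the %.0f%% missingness cap", 100 * max_missing)
    return kept


def encode_categoricals(
    table: pd.DataFrame, levels: dict[str, list] | None = None
) -> FeatureTable:
    """Full dummy coding: each k-level categorical becomes k indicator columns.

    Numeric columns pass through.  When ``levels`` is given (transform mode),
    unseen levels map to all-zero indicators with a warning.  Missing
    categorical entries yield NaN in every indicator of that variable, so
    downstream imputation sees them as missing.
    """
    cat_cols = [c for c in table.columns if table[c].dtype == object or str(table[c].dtype) == "category"]
    if levels is None:
        levels = {c: sorted(table[c].dropna().astype(str).unique().tolist()) for c in cat_cols}
    out: dict[str, pd.Series] = {}
    for c in table.columns:
        if c not in cat_cols:
            out[c] = pd.to_numeric(table[c])
            continue
        known = levels.get(c, [])
        col = table[c].astype(object)
        unseen = set(col.dropna().astype(str)) - set(known)
        if unseen:
            logger.warning("column %s: unseen levels %s mapped to all-zero indicators", c, sorted(unseen))
        for lev in known:
            vals = np.where(col.isna(), np.nan, (col.astype(str) == lev).astype(float))
            out[f"{c}={lev}"] = pd.Series(vals, index=table.index)
    return FeatureTable(data=pd.DataFrame(out, index=table.index), categorical_levels=levels)


def _pmm_numeric(y_obs, X_obs, X_mis, donors: int, rng) -> np.ndarray:
    """Predictive-mean matching: linear fit, match on predicted mean."""
    X_obs1 = np.column_stack([np.ones(len(X_obs)), X_obs])
    X_mis1 = np.column_stack([np.ones(len(X_mis)), X_mis])
    beta, *_ = np.linalg.lstsq(X_obs1, y_obs, rcond=None)
    yhat_obs = X_obs1 @ beta
    yhat_mis = X_mis1 @ beta
    return _match_donors(y_obs, yhat_obs, yhat_mis, donors, rng)


def _match_donors(y_obs, score_obs, score_mis, donors: int, rng) -> np.ndarray:
    k = min(donors, len(y_obs))
    out = np.empty(len(score_mis))
    for i, s in enumerate(score_mis):
        idx = np.argsort(np.abs(score_obs - s), kind="stable")[:k]
        out[i] = y_obs[idx[rng.integers(0, k)]]
    return out


def _pmm_indicator(y_obs, X_obs, X_mis, donors: int, rng) -> np.ndarray:
    """Logistic-score matching for binary indicator columns."""
    if len(np.unique(y_obs)) < 2:
        return np.full(len(X_mis), y_obs[0])
    clf = LogisticRegression(max_iter=200)
    clf.fit(X_obs, y_obs.astype(int))
    score_obs = clf.decision_function(X_obs)
    score_mis = clf.decision_function(X_mis)
    return _match_donors(y_obs, score_obs, score_mis, donors, rng).astype(float)


def impute_chained(
    table: FeatureTable | pd.DataFrame,
    m: int = 1,
    n_iter: int = 10,
    seed: int = 0,
    donors: int = 5,
) -> list[FeatureTable]:
    """Chained-equation multiple imputation with predictive-mean matching.

    Numeric columns: linear fit on all other columns, imputed values drawn
    from the ``donors`` observed values with nearest predicted mean (so
    imputations always lie in the observed support).  Binary indicator
    columns: logistic-score matching.  ``n_iter`` full sweeps; returns ``m``
    independently seeded completions.  Observed cells are preserved
    bit-exactly.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    df = table.data if isinstance(table, FeatureTable) else table
    tier = table.tier if isinstance(table, FeatureTable) else None
    fully_missing = [c for c in df.columns if df[c].isna().all()]
    if fully_missing:
        raise ValueError(f"column(s) fully missing, cannot impute: {fully_missing}")

    miss_cols = [c for c in df.columns if df[c].isna().any()]
    if not miss_cols:
        return [FeatureTable(df.copy(), tier=tier) for _ in range(m)]

    values = df.to_numpy(dtype=float)
    na_mask = np.isnan(values)
    is_indicator = np.array(
        [set(np.unique(values[~na_mask[:, j], j])) <= {0.0, 1.0} for j in range(values.shape[1])]
    )
    col_index = {c: j for j, c in enumerate(df.columns)}

    completions = []
    for rep in range(m):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]).generate_state(1)[0])
        work = values.copy()
        # Initial fill: observed mean (indicator columns: mode).
        for c in miss_cols:
            j = col_index[c]
            obs = work[~na_mask[:, j], j]
            fill = float(np.round(obs.mean())) if is_indicator[j] else float(obs.mean())
            work[na_mask[:, j], j] = fill
        for _ in range(n_iter):
            for c in miss_cols:
                j = col_index[c]
                mis = na_mask[:, j]
                others = np.delete(work, j, axis=1)
                y_obs = values[~mis, j]
                fn = _pmm_indicator if is_indicator[j] else _pmm_numeric
                work[mis, j] = fn(y_obs, others[~mis], others[mis], donors, rng)
        out = pd.DataFrame(work, index=df.index, columns=df.columns)
        # Preserve observed cells bit-exactly.
        out = out.where(na_mask, df)
        completions.append(FeatureTable(out, tier=tier))
    return completions


def build_tier(cohort: Cohort, imputed: FeatureTable, spec: TierSpec | str) -> FeatureTable:
    """Assemble one tier dataset from imputed admission features + daily data.

    ``D0`` is the imputed admission table itself; ``Dt`` appends day-stamped
    blood columns (``PT_d<k>``, lab values) for 0 < k <= t; ``DTIt`` appends
    the treatment flags ``treat_<name>_d<k>`` for 0 <= k <= t.  Column count
    is non-decreasing along D0 -> D7 and D -> DTI.
    """
    if isinstance(spec, str):
        spec = TierSpec.parse(spec)
    days = sorted({int(t) for p in cohort.patients for t in p.times})
    blood_days = [d for d in days if 0 < d <= spec.max_day]
    missing_days = [d for d in range(1, spec.max_day + 1) if d in (1, 2, 3, 7) and d not in days]
    if missing_days:
        raise ValueError(f"cohort day grid {days} lacks requested day(s) {missing_days}")

    ids = [p.id for p in cohort.patients]
    cols: dict[str, list] = {}
    for d in blood_days:
        cols[f"PT_d{d}"] = [p.pt_at(d) for p in cohort.patients]
        lab_names = sorted({k for p in cohort.patients for k in p.labs_daily.get(d, {})})
        for name in lab_names:
            cols[f"{name}_d{d}"] = [p.labs_daily.get(d, {}).get(name, np.nan) for p in cohort.patients]
    if spec.includes_treatment:
        tdays = [d for d in days if d <= spec.max_day]
        for name in TREATMENT_NAMES:
            for d in tdays:
                cols[f"treat_{name}_d{d}"] = [
                    float(p.treatments.get(name, {}).get(d, 0)) for p in cohort.patients
                ]
    extra = pd.DataFrame(cols, index=pd.Index(ids, name="id"))
    data = imputed.data.join(extra, how="left")
    return FeatureTable(data=data, tier=spec.tier, categorical_levels=imputed.categorical_levels)
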