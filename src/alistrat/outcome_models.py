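"""Supervised outcome and group-membership models.

* Random-forest classifiers under stratified 5-fold cross-validation, with
  SMOTE rebalancing applied inside each training fold only (oversampling
  before splitting would leak synthetic copies of test patients into
  training and inflate the AUC).
* Per-fold ROC/AUC, mean ROC by vertical averaging on a fixed 101-point FPR
  grid, fold-SD of the AUC.
* Exact TreeSHAP attribution of the final full-data model, computed on the
  original (unresampled) patients.
* The day-7 logistic PT% threshold: the PT% at which the fitted probability
  of non-TFS is 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from alistrat._treeshap import forest_shap_values

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierReport",
    "ThresholdModel",
    "ShapMatrix",
    "smote_oversample",
    "cv_rf_classify",
    "shap_attribution",
    "fit_logistic_threshold",
    "group_membership_models",
]

FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class ClassifierReport:
    per_fold_auc: list[float]
    auc_mean: float
    auc_sd: float
    mean_roc: tuple[np.ndarray, np.ndarray]  # (FPR grid, mean TPR)
    model_ref: object = field(repr=False, default=None)
    feature_names: list[str] | None = None


@dataclass
class ThresholdModel:
    intercept: float
    slope: float
    threshold: float
    cv_auc_mean: float | None = None
    cv_auc_sd: float | None = None
    separation_flag: bool = False

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("slope must be negative (higher PT% -> lower non-TFS probability)")


@dataclass
class ShapMatrix:
    values: np.ndarray      # n x p attribution matrix
    base_value: float
    feature_names: list[str]
    scores: np.ndarray      # model scores on the same rows

    def mean_abs(self) -> pd.Series:
        return pd.Series(np.abs(self.values).mean(axis=0), index=self.feature_names).sort_values(
            ascending=False
        )


def smote_oversample(X, y, k_neighbors: int = 5, seed: int = 0):
    """Synthetic minority oversampling to balanced class counts.

    Each synthetic row is ``x_i + u * (x_nn - x_i)`` with ``u ~ U(0,1)`` and
    ``x_nn`` one of the ``k_neighbors`` nearest minority neighbors of
    ``x_i`` (Euclidean; k clipped to minority size - 1).  Original rows are
    preserved, majority rows untouched.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("y must contain both classes")
    if classes.size > 2:
        raise ValueError("binary labels expected")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    deficit = int(n_maj - n_min)
    if deficit == 0:
        return X.copy(), y.copy()
    if n_min < 2:
        raise ValueError("minority class needs >= 2 members for interpolation")
    rng = np.random.default_rng(seed)
    Xm = X[y == minority]
    k = int(min(k_neighbors, n_min - 1))
    d = np.linalg.norm(Xm[:, None, :] - Xm[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    nn = np.argsort(d, axis=1, kind="stable")[:, :k]
    base_idx = rng.integers(0, n_min, size=deficit)
    nbr_idx = nn[base_idx, rng.integers(0, k, size=deficit)]
    u = rng.random(deficit)[:, None]
    synth = Xm[base_idx] + u * (Xm[nbr_idx] - Xm[base_idx])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(deficit, minority, dtype=y.dtype)])
    return X_out, y_out


def _resample_and_fit(X, y, n_trees, k_neighbors, seed):
    Xb, yb = smote_oversample(X, y, k_neighbors=k_neighbors, seed=seed)
    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", oob_score=False, random_state=seed, n_jobs=1
    )
    rf.fit(Xb, yb)
    return rf


def cv_rf_classify(
    X,
    y,
    n_folds: int = 5,
    seed: int = 0,
    n_trees: int = 500,
    k_neighbors: int = 5,
    feature_names: list[str] | None = None,
) -> ClassifierReport:
    """Stratified k-fold RF classification with in-fold SMOTE.

    Returns per-fold AUCs, their mean/SD, the vertically averaged ROC on a
    101-point FPR grid, and a final model refit on the full (resampled) data
    for SHAP attribution.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(f"minority count {counts.min()} < n_folds {n_folds}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs, tprs = [], []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        rf = _resample_and_fit(X[tr], y[tr], n_trees, k_neighbors, seed + fold)
        score = rf.predict_proba(X[te])[:, 1]
        aucs.append(float(roc_auc_score(y[te], score)))
        fpr, tpr, _ = roc_curve(y[te], score)
        tprs.append(np.interp(FPR_GRID, fpr, tpr))
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    final = _resample_and_fit(X, y, n_trees, k_neighbors, seed)
    return ClassifierReport(
        per_fold_auc=aucs,
        auc_mean=float(np.mean(aucs)),
        auc_sd=float(np.std(aucs)),
        mean_roc=(FPR_GRID.copy(), mean_tpr),
        model_ref=final,
        feature_names=feature_names,
    )


def shap_attribution(model_ref, X_original, feature_names: list[str] | None = None) -> ShapMatrix:
    """Exact TreeSHAP attribution of a fitted forest on unresampled patients."""
    if isinstance(X_original, pd.DataFrame):
        feature_names = feature_names or list(X_original.columns)
        X_original = X_original.to_numpy(dtype=float)
    X_original = np.asarray(X_original, dtype=float)
    if X_original.shape[1] != model_ref.n_features_in_:
        raise ValueError(
            f"feature mismatch: model expects {model_ref.n_features_in_}, got {X_original.shape[1]}"
        )
    phi, base = forest_shap_values(model_ref, X_original, class_index=1)
    scores = model_ref.predict_proba(X_original)[:, 1]
    names = feature_names or [f"x{j}" for j in range(X_original.shape[1])]
    return ShapMatrix(values=phi, base_value=float(base), feature_names=names, scores=scores)


def fit_logistic_threshold(
    pt_day7, labels, seed: int = 0, n_folds: int = 5, with_cv: bool = True
) -> ThresholdModel:
    """Day-7 PT% logistic threshold for non-TFS.

    Fits an L2-regularized logistic regression (C=1.0, unstandardized
    predictor) of non-TFS on day-7 PT% using all patients, and reports the
    PT% at which the fitted probability is 0.5 (``-intercept/slope``).
    Optionally also reports the SMOTE-rebalanced stratified-CV AUC.
    """
    pt = np.asarray(pt_day7, dtype=float).reshape(-1, 1)
    y = np.asarray([1 if lab in (1, "non-TFS") else 0 for lab in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes required")
    clf = LogisticRegression(C=1.0, max_iter=1000)
    clf.fit(pt, y)
    slope = float(clf.coef_[0, 0])
    intercept = float(clf.intercept_[0])
    # Complete separation shows up as extreme fitted probabilities everywhere.
    p = clf.predict_proba(pt)[:, 1]
    sep = bool(np.all((p < 1e-4) | (p > 1 - 1e-4)))
    auc_mean = auc_sd = None
    if with_cv:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        aucs = []
        for fold, (tr, te) in enumerate(skf.split(pt, y)):
            Xb, yb = smote_oversample(pt[tr], y[tr], seed=seed + fold)
            m = LogisticRegression(C=1.0, max_iter=1000).fit(Xb, yb)
            aucs.append(float(roc_auc_score(y[te], m.predict_proba(pt[te])[:, 1])))
        auc_mean, auc_sd = float(np.mean(aucs)), float(np.std(aucs))
    return ThresholdModel(
        intercept=intercept,
        slope=slope,
        threshold=-intercept / slope,
        cv_auc_mean=auc_mean,
        cv_auc_sd=auc_sd,
        separation_flag=sep,
    )


def group_membership_models(
    X,
    group_labels,
    groups=("G3", "G4", "G5", "G6"),
    seed: int = 0,
    n_folds: int = 5,
    n_trees: int = 500,
    feature_names: list[str] | None = None,
) -> dict[str, ClassifierReport]:
    """One-vs-rest RF classifiers for trajectory-group membership.

    G1/G2 are excluded by default: admission PT% alone separates them, so
    the interesting prediction problem is which of the severe strata a
    low-PT% patient belongs to.  Groups absent from the labels are skipped
    with a warning.
    """
    group_labels = np.asarray(group_labels)
    out: dict[str, ClassifierReport] = {}
    for g in groups:
        yb = (group_labels == g).astype(int)
        if yb.sum() < n_folds or yb.sum() == len(yb):
            logger.warning("group %s absent or too small for %d-fold CV; skipped", g, n_folds)
            continue
        out[g] = cv_rf_classify(
            X, yb, n_folds=n_folds, seed=seed, n_trees=n_trees, feature_names=feature_names
        )
    return out
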