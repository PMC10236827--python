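"""The three fusion schemes over the two calibrated base models.

* soft-voting ensemble — the arithmetic mean of the two rescaled
  probabilities, thresholded at 0.50;
* hierarchical (stacked) model — a second-level random forest trained on
  the two out-of-fold rescaled probabilities;
* similarity-based merger — a logistic regression over four features: both
  rescaled probabilities plus the compound's structural and morphological
  similarity to active training compounds.  The similarity features let
  the logistic model weight each base model by how far the compound sits
  from that model's applicability domain.

All mergers are fitted exclusively on out-of-fold features of the training
split; no held-out hit call ever enters a fit.  Ties at probability 0.50
are called active everywhere, mirroring the base learners' ``p >= t`` rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

MERGER_FEATURES = ["p_struct_scaled", "p_morph_scaled", "s_struct", "s_morph"]
HIERARCHICAL_FEATURES = ["p_struct_scaled", "p_morph_scaled"]
HIERARCHICAL_ESTIMATOR_GRID = (100, 300, 400, 500)


@dataclass
class MergerConfig:
    """Logistic-regression settings: L2 penalty, inverse regularization
    strength C (default 1.0), balanced class weights."""

    inverse_regularization: float = 1.0

    def __post_init__(self) -> None:
        if self.inverse_regularization <= 0:
            raise ValueError("inverse_regularization must be > 0")


@dataclass
class MergerModel:
    """Similarity-based merger: logistic coefficients over the 4 features.

    The model is fully described by its intercept and coefficient vector;
    prediction evaluates the logistic link directly, so a merger restored
    from an exported manifest predicts identically to the freshly fitted
    one.
    """

    intercept: float
    coefficients: dict[str, float]
    fitted: bool = False


@dataclass
class HierarchicalModel:
    """Fitted second-level classifier over the two rescaled probabilities."""

    n_estimators: int
    class_weight: Any
    _model: Any = field(default=None, repr=False)


def _check_unit_interval(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError(f"{name} must lie in [0, 1]")
    return p


def soft_vote(p_struct, p_morph) -> tuple[np.ndarray | float, np.ndarray | int]:
    """Soft-voting ensemble: mean of the two rescaled probabilities.

    Returns ``(probability, call)`` with the call active iff the mean is
    >= 0.50.  Symmetric in its two inputs; accepts scalars or arrays.
    """
    scalar = np.isscalar(p_struct) and np.isscalar(p_morph)
    ps = _check_unit_interval(p_struct, "p_struct")
    pm = _check_unit_interval(p_morph, "p_morph")
    prob = (ps + pm) / 2.0
    call = (prob >= 0.5).astype(int)
    if scalar:
        return float(prob), int(call)
    return prob, call


def fit_hierarchical(oof: pd.DataFrame, seed: int, n_folds: int = 5) -> HierarchicalModel:
    """Fit the stacked baseline on out-of-fold rescaled probabilities.

    The estimator count is tuned over {100, 300, 400, 500} x class
    weighting {None, balanced} by seeded stratified k-fold CV AUC, then the
    forest is refitted on all out-of-fold rows.
    """
    X = oof[HIERARCHICAL_FEATURES].to_numpy()
    y = oof["y"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("fit_hierarchical requires both classes present")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    best, best_score = None, -np.inf
    for n_estimators in HIERARCHICAL_ESTIMATOR_GRID:
        for class_weight in (None, "balanced"):
            scores = []
            for tr, te in cv.split(X, y):
                rf = RandomForestClassifier(
                    n_estimators=n_estimators, class_weight=class_weight,
                    random_state=seed, n_jobs=1,
                )
                rf.fit(X[tr], y[tr])
                scores.append(roc_auc_score(y[te], rf.predict_proba(X[te])[:, 1]))
            score = float(np.mean(scores))
            if score > best_score:
                best_score = score
                best = (n_estimators, class_weight)
    n_estimators, class_weight = best
    rf = RandomForestClassifier(
        n_estimators=n_estimators, class_weight=class_weight,
        random_state=seed, n_jobs=1,
    )
    rf.fit(X, y)
    return HierarchicalModel(n_estimators=n_estimators, class_weight=class_weight,
                             _model=rf)


def predict_hierarchical(m: HierarchicalModel, features: pd.DataFrame):
    """Probability and 0.50-threshold call from the stacked baseline."""
    if m._model is None:
        raise ValueError("hierarchical model is not fitted")
    prob = m._model.predict_proba(features[HIERARCHICAL_FEATURES].to_numpy())[:, 1]
    return prob, (prob >= 0.5).astype(int)


def fit_similarity_merger(oof: pd.DataFrame, cfg: MergerConfig | None = None) -> MergerModel:
    """Fit the similarity-based merger on out-of-fold features.

    A logistic regression (L2 penalty, C = ``inverse_regularization``,
    balanced class weights) over the four merger features against the
    training hit calls.  Features are used raw: two are probabilities in
    [0, 1], s_struct is in [0, 1] and s_morph in [-1, 1].
    """
    cfg = cfg or MergerConfig()
    X = oof[MERGER_FEATURES].to_numpy()
    y = oof["y"].to_numpy()
    if not np.isfinite(X).all():
        raise ValueError("merger features must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("fit_similarity_merger requires both classes present")
    # L2 penalty (the sklearn default), strength 1/C, balanced class weights
    lr = LogisticRegression(
        C=cfg.inverse_regularization,
        class_weight="balanced",
        solver="lbfgs",
        max_iter=5000,
        tol=1e-10,
    )
    lr.fit(X, y)
    return MergerModel(
        intercept=float(lr.intercept_[0]),
        coefficients={name: float(c) for name, c in zip(MERGER_FEATURES, lr.coef_[0])},
        fitted=True,
    )


def predict_merger(m: MergerModel, features: pd.DataFrame):
    """Probability and 0.50-threshold call from the similarity merger.

    The probability is the standard logistic link over the four features;
    the call is active iff the probability is >= 0.50.
    """
    if not m.fitted:
        raise ValueError("merger model is not fitted")
    X = features[MERGER_FEATURES].to_numpy(dtype=float)
    w = np.array([m.coefficients[name] for name in MERGER_FEATURES])
    prob = expit(X @ w + m.intercept)
    return prob, (prob >= 0.5).astype(int)
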