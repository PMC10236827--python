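"""Calibrated base classifiers and the nested cross-validation stacker.

One random-forest classifier is trained per feature space (fingerprints,
morphology).  Because assays are imbalanced even after 3:1 undersampling,
the raw predicted probability is not thresholded at 0.5; instead the
decision threshold ``t`` maximising Youden's J statistic (J = TPR - FPR)
is estimated from cross-validated predictions on the training data, and
probabilities are min-max rescaled piecewise so that ``t`` maps to 0.50:

    scaled(p) = 0.5 * p / t              if p <= t
    scaled(p) = 0.5 + 0.5 * (p-t)/(1-t)  if p > t

The rescaling is strictly increasing, fixes the endpoints 0 and 1, and the
call ``p >= t`` is equivalent to ``scaled(p) >= 0.5``, so every downstream
consumer can threshold at 0.50.

:func:`run_nested_cv` produces the out-of-fold stacking features: each of
the five outer folds is predicted by models tuned, fitted and calibrated on
the other four, and each held-aside compound additionally receives its
structural/morphological similarity to the *actives of the other four
folds* — no label of a compound's own fold ever touches the features
recorded for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterGrid, ParameterSampler, StratifiedKFold, cross_val_predict

from .config import RunConfig
from .similarity import SimilarityConfig, score_compound_set

EPS = 1e-6


@dataclass
class CalibrationResult:
    """Youden-optimal threshold and the J statistic it attains."""

    threshold: float
    j: float


@dataclass
class HyperparameterSpace:
    """Candidate grid for the randomized hyperparameter search."""

    params: dict[str, list[Any]]
    n_iter: int = 20

    def __post_init__(self) -> None:
        if not self.params or any(len(v) == 0 for v in self.params.values()):
            raise ValueError("hyperparameter space must be non-empty")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")

    @property
    def n_candidates(self) -> int:
        out = 1
        for v in self.params.values():
            out *= len(v)
        return out


def default_space() -> HyperparameterSpace:
    """Default random-forest search grid (fully user-overridable)."""
    return HyperparameterSpace(
        params={
            "n_estimators": [100, 300, 500],
            "max_depth": [None, 10, 20],
            "min_samples_leaf": [1, 3, 5],
            "max_features": ["sqrt", 0.3],
            "class_weight": [None, "balanced"],
        },
        n_iter=20,
    )


def compact_space() -> HyperparameterSpace:
    """Single-candidate space for desk-scale benchmark runs.

    With one candidate the tuning step is a no-op, which keeps the
    30-assay synthetic benchmark tractable on a single core while leaving
    the calibration and stacking machinery fully exercised.
    """
    return HyperparameterSpace(
        params={"n_estimators": [100], "class_weight": ["balanced"]},
        n_iter=1,
    )


def youden_threshold(y: np.ndarray, p: np.ndarray) -> CalibrationResult:
    """Youden-optimal decision threshold from labels and probabilities.

    Candidate thresholds are the unique values of ``p``; a compound is
    called positive iff ``p >= t``.  Returns the candidate maximising
    J = TPR - FPR, ties resolved to the smallest threshold, clamped into
    ``(1e-6, 1 - 1e-6)``.
    """
    y = np.asarray(y)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and p must have the same length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("youden_threshold requires both classes present")
    # Sort descending; at threshold t = p_sorted[i], everything with
    # p >= t is called positive -> cumulative class counts give TPR/FPR.
    order = np.argsort(-p, kind="stable")
    ps = p[order]
    ys = y[order]
    tp = np.cumsum(ys == 1)
    fp = np.cumsum(ys == 0)
    # last occurrence of each unique threshold value in the sorted array
    last = np.flatnonzero(np.r_[ps[1:] != ps[:-1], True])
    cand = ps[last]
    j = tp[last] / n_pos - fp[last] / n_neg
    best_j = j.max()
    # ties -> smallest threshold; cand is descending, so take the last max
    t = float(cand[np.flatnonzero(j == best_j)[-1]])
    t = min(max(t, EPS), 1.0 - EPS)
    return CalibrationResult(threshold=t, j=float(best_j))


def rescale_probability(p, t: float):
    """Min-max rescale probabilities so the threshold ``t`` maps to 0.50.

    Piecewise linear, strictly increasing, endpoint-preserving.  Accepts a
    scalar or array; returns the same shape.
    """
    if not 0.0 < t < 1.0:
        raise ValueError(f"threshold must lie strictly inside (0, 1), got {t}")
    p_arr = np.asarray(p, dtype=float)
    if ((p_arr < 0) | (p_arr > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    out = np.where(p_arr <= t, 0.5 * p_arr / t, 0.5 + 0.5 * (p_arr - t) / (1.0 - t))
    return float(out) if np.isscalar(p) else out


def make_classifier(params: dict[str, Any], seed: int) -> RandomForestClassifier:
    """The base learner: a random forest with the given hyperparameters."""
    return RandomForestClassifier(random_state=seed, n_jobs=1, **params)


def tune_classifier(
    X: np.ndarray,
    y: np.ndarray,
    space: HyperparameterSpace,
    n_folds: int,
    seed: int,
) -> dict[str, Any]:
    """Randomized hyperparameter search scored by stratified-CV AUC.

    Samples ``min(n_iter, n_candidates)`` parameter sets without
    replacement and returns the one with the best mean ROC AUC over a
    seeded, shuffled stratified k-fold; deterministic under a fixed seed.
    A single-candidate space is returned directly without fitting.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be 2-D with at least one feature")
    if len(np.unique(y)) < 2:
        raise ValueError("tune_classifier requires both classes present")
    if space.n_candidates == 1:
        return dict(next(iter(ParameterGrid(space.params))))
    n_iter = min(space.n_iter, space.n_candidates)
    candidates = list(ParameterSampler(space.params, n_iter=n_iter, random_state=seed))
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    best_params, best_score = None, -np.inf
    for params in candidates:
        scores = []
        for tr, te in cv.split(X, y):
            model = make_classifier(params, seed)
            model.fit(X[tr], y[tr])
            scores.append(roc_auc_score(y[te], model.predict_proba(X[te])[:, 1]))
        score = float(np.mean(scores))
        if score > best_score:  # strict: first of tied candidates wins
            best_score, best_params = score, params
    return dict(best_params)


@dataclass
class CalibratedModel:
    """A fitted classifier plus its Youden calibration.

    ``predict_scaled`` returns probabilities on the rescaled axis where the
    optimal threshold sits at 0.50; ``rescale(t) == 0.5`` exactly.
    """

    estimator: Any
    tag: str  # "struct" | "morph"
    calibration: CalibrationResult
    params: dict[str, Any] = field(default_factory=dict)
    feature_names: list[str] = field(default_factory=list)

    def predict_proba_raw(self, X) -> np.ndarray:
        return self.estimator.predict_proba(np.asarray(X))[:, 1]

    def predict_scaled(self, X) -> np.ndarray:
        return rescale_probability(self.predict_proba_raw(X), self.calibration.threshold)


def _cv_probabilities(
    X: np.ndarray, y: np.ndarray, params: dict, n_folds: int, seed: int
) -> np.ndarray:
    model = make_classifier(params, seed)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return cross_val_predict(model, X, y, cv=cv, method="predict_proba", n_jobs=1)[:, 1]


def fit_final_model(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    tag: str,
    cfg: RunConfig,
    space: HyperparameterSpace | None = None,
    assay_id: str = "",
) -> CalibratedModel:
    """Tune, calibrate and fit one base model on the full training split.

    The Youden threshold comes from stratified cross-validated predictions
    on the training data; the classifier itself is then refitted on all
    training rows.
    """
    space = space or default_space()
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else []
    X = np.asarray(X)
    y = np.asarray(y)
    seed = cfg.stage_seed(f"final:{tag}:{assay_id}")
    params = tune_classifier(X, y, space, cfg.n_inner_folds, seed)
    p_cv = _cv_probabilities(X, y, params, cfg.n_inner_folds, seed)
    calibration = youden_threshold(y, p_cv)
    model = make_classifier(params, seed)
    model.fit(X, y)
    return CalibratedModel(
        estimator=model,
        tag=tag,
        calibration=calibration,
        params=params,
        feature_names=feature_names,
    )


OOF_COLUMNS = ["compound_id", "fold", "p_struct_scaled", "p_morph_scaled",
               "s_struct", "s_morph", "y"]


def run_nested_cv(
    X_struct: pd.DataFrame | np.ndarray,
    X_morph: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    compound_ids: list[str],
    cfg: RunConfig,
    space: HyperparameterSpace | None = None,
    sim_cfg: SimilarityConfig | None = None,
    assay_id: str = "",
    folds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Out-of-fold stacking features over the training split.

    For each outer fold: tune and fit both base models on the remaining
    folds, calibrate their thresholds on cross-validated predictions within
    those folds, predict the held-aside fold on the rescaled axis, and
    score each held-aside compound's similarity to the actives of the
    remaining folds.  The concatenated result covers every training
    compound exactly once.

    ``folds`` may supply a precomputed fold assignment (array of fold
    indices per row); by default a seeded stratified k-fold is used.
    """
    space = space or default_space()
    sim_cfg = sim_cfg or SimilarityConfig()
    Xs = np.asarray(X_struct)
    Xm = np.asarray(X_morph)
    y = np.asarray(y)
    n = len(y)
    if folds is None:
        folds = np.empty(n, dtype=int)
        skf = StratifiedKFold(
            n_splits=cfg.n_outer_folds,
            shuffle=True,
            random_state=cfg.stage_seed(f"outer:{assay_id}"),
        )
        for f, (_, te) in enumerate(skf.split(Xs, y)):
            folds[te] = f
    folds = np.asarray(folds)

    records = []
    for f in np.unique(folds):
        te = np.flatnonzero(folds == f)
        tr = np.flatnonzero(folds != f)
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"outer fold {f}: training part has a single class")
        scaled = {}
        for tag, X in (("struct", Xs), ("morph", Xm)):
            seed = cfg.stage_seed(f"nested:{tag}:{assay_id}:{f}")
            params = tune_classifier(X[tr], y[tr], space, cfg.n_inner_folds, seed)
            p_cv = _cv_probabilities(X[tr], y[tr], params, cfg.n_inner_folds, seed)
            cal = youden_threshold(y[tr], p_cv)
            model = make_classifier(params, seed)
            model.fit(X[tr], y[tr])
            scaled[tag] = rescale_probability(model.predict_proba(X[te])[:, 1],
                                              cal.threshold)
        actives = tr[y[tr] == 1]
        sims = score_compound_set(Xs[te], Xm[te], Xs[actives], Xm[actives], sim_cfg)
        block = pd.DataFrame({
            "compound_id": [compound_ids[i] for i in te],
            "fold": f,
            "p_struct_scaled": scaled["struct"],
            "p_morph_scaled": scaled["morph"],
            "s_struct": sims["s_struct"].to_numpy(),
            "s_morph": sims["s_morph"].to_numpy(),
            "y": y[te],
        })
        records.append(block)
    return pd.concat(records, ignore_index=True)[OOF_COLUMNS]
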