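"""Metrics, paired cross-assay testing, and applicability-domain binning.

Per assay and model we report precision, sensitivity, minority-class F1,
specificity, balanced accuracy, Matthews correlation coefficient and ROC
AUC.  AUC is computed by the Mann-Whitney rank statistic with midrank tie
handling, which makes it invariant under any strictly monotone transform
of the probabilities — in particular identical before and after threshold
rescaling.

Cross-assay model comparison uses a two-sided paired t-test on per-assay
metric values; an assay enters the comparison only if at least one of the
two models achieved balanced accuracy > 0.50 and minority-class F1 > 0.

The applicability-domain analysis bins held-out compounds by their
similarity to active training compounds (width-0.1 half-open bins, top bin
closed) and reports the fraction correctly classified per bin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

METRIC_NAMES = ["precision", "sensitivity", "f1_minority", "specificity",
                "balanced_accuracy", "mcc", "auc"]


def auc_score(y: np.ndarray, p: np.ndarray) -> float:
    """ROC AUC via the Mann-Whitney rank formulation (midrank ties)."""
    y = np.asarray(y)
    p = np.asarray(p, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(p, method="average")
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_metrics(y: np.ndarray, call: np.ndarray, p: np.ndarray | None = None) -> dict:
    """Standard binary-classification metrics for one assay and model.

    Precision, sensitivity and specificity are reported for the active
    (positive) class; F1 for whichever class is the minority.  AUC needs
    probabilities and both classes; it is NaN otherwise.
    """
    y = np.asarray(y)
    call = np.asarray(call)
    if y.shape != call.shape:
        raise ValueError("y and call must be aligned")
    tp = int(((y == 1) & (call == 1)).sum())
    fp = int(((y == 0) & (call == 1)).sum())
    fn = int(((y == 1) & (call == 0)).sum())
    tn = int(((y == 0) & (call == 0)).sum())

    def ratio(a: float, b: float) -> float:
        return a / b if b else 0.0

    precision = ratio(tp, tp + fp)
    sensitivity = ratio(tp, tp + fn)
    specificity = ratio(tn, tn + fp)
    balanced_accuracy = (sensitivity + specificity) / 2.0

    # F1 of the minority class (ties go to the positive class)
    if (y == 1).sum() <= (y == 0).sum():
        prec_min, rec_min = precision, sensitivity
    else:
        prec_min = ratio(tn, tn + fn)
        rec_min = specificity
    f1_minority = ratio(2 * prec_min * rec_min, prec_min + rec_min)

    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0

    auc = auc_score(y, p) if p is not None else float("nan")
    return {
        "precision": precision,
        "sensitivity": sensitivity,
        "f1_minority": f1_minority,
        "specificity": specificity,
        "balanced_accuracy": balanced_accuracy,
        "mcc": float(mcc),
        "auc": auc,
    }


def comparison_mask(metrics_a: pd.DataFrame, metrics_b: pd.DataFrame) -> np.ndarray:
    """Inclusion rule for paired testing: keep an assay iff at least one of
    the two models has balanced accuracy > 0.50 and minority F1 > 0."""
    ok_a = (metrics_a["balanced_accuracy"] > 0.5) & (metrics_a["f1_minority"] > 0)
    ok_b = (metrics_b["balanced_accuracy"] > 0.5) & (metrics_b["f1_minority"] > 0)
    return (ok_a | ok_b).to_numpy()


def paired_comparison(metric_a, metric_b) -> tuple[float, float, int]:
    """Two-sided paired t-test on per-assay metric values.

    Returns ``(t, p, n)``.  Raises on fewer than two assays or on
    zero-variance differences (the t statistic is undefined there).
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("metric vectors must be aligned by assay")
    if len(a) < 2:
        raise ValueError("paired comparison needs at least 2 assays")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        raise ValueError("paired differences have zero variance; t-test undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), len(a)


def bin_by_similarity(
    predictions: pd.DataFrame,
    axis: str,
    width: float = 0.1,
) -> pd.DataFrame:
    """Fraction of correct calls per similarity bin.

    Parameters
    ----------
    predictions
        Must carry a ``correct`` flag column and the similarity column for
        the chosen axis (``s_struct`` or ``s_morph``).
    axis
        ``"struct"`` bins s_struct over [0, 1]; ``"morph"`` bins s_morph
        over [-1, 1].

    Bins are half-open ``[lo, lo+width)`` except the top bin, which is
    closed so a score at the upper edge is counted once.  Empty bins are
    emitted with ``n = 0`` and NaN fraction.
    """
    if axis == "struct":
        col, lo, hi = "s_struct", 0.0, 1.0
    elif axis == "morph":
        col, lo, hi = "s_morph", -1.0, 1.0
    else:
        raise ValueError(f"axis must be 'struct' or 'morph', got {axis!r}")
    scores = predictions[col].to_numpy(dtype=float)
    correct = predictions["correct"].to_numpy(dtype=bool)
    n_bins = int(round((hi - lo) / width))
    edges = lo + width * np.arange(n_bins + 1)
    idx = np.clip(np.floor((scores - lo) / width).astype(int), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        n = int(mask.sum())
        frac = float(correct[mask].mean()) if n else float("nan")
        rows.append({"axis": axis, "lo": edges[b], "hi": edges[b + 1],
                     "n": n, "fraction_correct": frac})
    return pd.DataFrame(rows)
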