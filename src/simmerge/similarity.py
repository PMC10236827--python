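"""Applicability-domain similarity scores against active training compounds.

Two scores summarise how close a query compound sits to the active part of
the training set, one per feature space:

* structural — the mean Tanimoto similarity of the query's fingerprint to
  its ``k`` most similar active training compounds (``k`` = 5 by default);
* morphological — the median Pearson correlation of the query's profile to
  its ``k`` most positively correlated active training compounds.

When fewer than ``k`` actives exist the statistic runs over all of them.
Both scores are pure functions of the value multiset, so they are invariant
to the ordering of the active set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SimilarityConfig:
    """Number of nearest active neighbours entering each score."""

    k: int = 5

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity of two binary vectors.

    Defined as ``|a AND b| / |a OR b|``; 0 when both vectors are all-zero.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    inter = int(np.sum((a != 0) & (b != 0)))
    union = int(np.sum((a != 0) | (b != 0)))
    return inter / union if union else 0.0


def tanimoto_matrix(Q: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarities, queries x actives."""
    Q = (np.asarray(Q) != 0).astype(np.int64)
    A = (np.asarray(A) != 0).astype(np.int64)
    if Q.shape[1] != A.shape[1]:
        raise ValueError("fingerprint width mismatch between queries and actives")
    inter = Q @ A.T
    union = Q.sum(axis=1)[:, None] + A.sum(axis=1)[None, :] - inter
    out = np.zeros(inter.shape, dtype=float)
    np.divide(inter, union, out=out, where=union > 0)
    return out


def pearson_matrix(Q: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations, queries x actives.

    A pair involving a zero-variance vector correlates 0 (convention; never
    NaN).
    """
    Q = np.asarray(Q, dtype=float)
    A = np.asarray(A, dtype=float)
    if Q.shape[1] != A.shape[1]:
        raise ValueError("profile width mismatch between queries and actives")
    n = Q.shape[1]

    def standardize(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sd = M.std(axis=1)
        Z = M - M.mean(axis=1, keepdims=True)
        ok = sd > 0
        Z[ok] /= sd[ok, None]
        Z[~ok] = 0.0
        return Z, ok

    Zq, okq = standardize(Q)
    Za, oka = standardize(A)
    r = (Zq @ Za.T) / n
    r[~okq, :] = 0.0
    r[:, ~oka] = 0.0
    return np.clip(r, -1.0, 1.0)


def _top_k(values: np.ndarray, k: int) -> np.ndarray:
    """The k algebraically largest values (all of them if fewer than k)."""
    k = min(k, values.shape[-1])
    return np.sort(values, axis=-1)[..., -k:]


def structural_similarity_score(
    q: np.ndarray, actives: np.ndarray, cfg: SimilarityConfig | None = None
) -> float:
    """Mean Tanimoto similarity of the query to its k most similar actives."""
    cfg = cfg or SimilarityConfig()
    actives = np.atleast_2d(actives)
    if actives.shape[0] == 0:
        raise ValueError("structural similarity undefined for an empty active set")
    sims = tanimoto_matrix(np.atleast_2d(q), actives)[0]
    return float(_top_k(sims, cfg.k).mean())


def morphological_similarity_score(
    q: np.ndarray, actives: np.ndarray, cfg: SimilarityConfig | None = None
) -> float:
    """Median Pearson correlation of the query to its k most positively
    correlated actives."""
    cfg = cfg or SimilarityConfig()
    actives = np.atleast_2d(actives)
    if actives.shape[0] == 0:
        raise ValueError("morphological similarity undefined for an empty active set")
    corrs = pearson_matrix(np.atleast_2d(q), actives)[0]
    return float(np.median(_top_k(corrs, cfg.k)))


def score_compound_set(
    queries_struct: np.ndarray,
    queries_morph: np.ndarray,
    actives_struct: np.ndarray,
    actives_morph: np.ndarray,
    cfg: SimilarityConfig | None = None,
    index: pd.Index | None = None,
) -> pd.DataFrame:
    """Both similarity scores for a batch of query compounds.

    Vectorised; equals the per-compound scalar calls exactly.  Returns a
    DataFrame with columns ``s_struct`` and ``s_morph``.
    """
    cfg = cfg or SimilarityConfig()
    Qs = np.atleast_2d(queries_struct)
    Qm = np.atleast_2d(queries_morph)
    if Qs.shape[0] != Qm.shape[0]:
        raise ValueError("structural and morphological query counts differ")
    As = np.atleast_2d(actives_struct)
    Am = np.atleast_2d(actives_morph)
    if As.shape[0] == 0 or Am.shape[0] == 0:
        raise ValueError("similarity scores undefined for an empty active set")
    s_struct = _top_k(tanimoto_matrix(Qs, As), cfg.k).mean(axis=1)
    s_morph = np.median(_top_k(pearson_matrix(Qm, Am), cfg.k), axis=1)
    return pd.DataFrame({"s_struct": s_struct, "s_morph": s_morph}, index=index)
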