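"""The two feature spaces: circular fingerprints and morphological profiles.

Structures are encoded as hashed circular (Morgan) fingerprints of radius 2
over 2048 binary bits; the hashing itself is delegated to RDKit, which is an
optional dependency — precomputed binary matrices are first-class inputs and
the rest of the pipeline never touches a cheminformatics toolkit.

Morphological profiles arrive as well-level, plate-normalised feature
vectors.  :func:`aggregate_profiles` subtracts each plate's neutral-control
mean and collapses dose replicates to a per-compound median over the doses
within one standard deviation of the mean dose.  Feature selection then
applies, in order: a user-supplied blocklist, a variance floor, greedy
pruning of correlated pairs, and a cap on the maximum absolute value.
Fingerprint bits are filtered with a near-zero-variance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RAW_META_COLUMNS = ("compound_id", "plate_id", "dose", "is_control")


@dataclass
class FeatureSelectionConfig:
    """Thresholds for morphology/fingerprint feature selection.

    Defaults follow common practice for CellProfiler-derived profiles:
    variance floor 0.005, pairwise |Pearson r| cap 0.9, maximum absolute
    value 15, and a 0.05 near-zero-variance floor for fingerprint bits.
    """

    blocklist: frozenset[str] = field(default_factory=frozenset)
    variance_threshold: float = 0.005
    correlation_threshold: float = 0.9
    max_abs_value: float = 15.0
    fp_variance_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.variance_threshold < 0 or self.fp_variance_threshold < 0:
            raise ValueError("variance thresholds must be >= 0")
        if not 0.0 < self.correlation_threshold <= 1.0:
            raise ValueError("correlation_threshold must lie in (0, 1]")
        if self.max_abs_value < 0:
            raise ValueError("max_abs_value must be >= 0")
        self.blocklist = frozenset(self.blocklist)


def compute_fingerprints(
    smiles: "pd.Series | list[str] | dict[str, str]",
    radius: int = 2,
    n_bits: int = 2048,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hashed circular fingerprints for a set of structures.

    Parameters
    ----------
    smiles
        Mapping of compound_id -> SMILES (dict or pandas Series); a plain
        list is keyed by position.
    radius, n_bits
        Circular fingerprint radius and bit-vector width.

    Returns
    -------
    (matrix, rejects)
        ``matrix`` is a binary uint8 DataFrame indexed by compound_id with
        columns ``fp_0000 .. fp_{n_bits-1}``.  ``rejects`` lists compounds
        whose SMILES could not be parsed (columns compound_id, smiles,
        reason); they are absent from the matrix and the run continues.
    """
    try:
        from rdkit import Chem, RDLogger
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError(
            "compute_fingerprints requires rdkit; install the 'chem' extra "
            "or supply a precomputed fingerprint matrix"
        ) from exc
    RDLogger.DisableLog("rdApp.error")

    if isinstance(smiles, dict):
        items = list(smiles.items())
    elif isinstance(smiles, pd.Series):
        items = list(smiles.items())
    else:
        items = [(str(i), s) for i, s in enumerate(smiles)]

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    rows, ids, rejects = [], [], []
    for cid, smi in items:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            rejects.append({"compound_id": str(cid), "smiles": smi,
                            "reason": "unparseable SMILES"})
            continue
        fp = gen.GetFingerprintAsNumPy(mol)
        rows.append(np.asarray(fp, dtype=np.uint8))
        ids.append(str(cid))
    columns = [f"fp_{i:04d}" for i in range(n_bits)]
    matrix = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, n_bits), dtype=np.uint8),
        index=pd.Index(ids, name="compound_id"),
        columns=columns,
    )
    return matrix, pd.DataFrame(rejects, columns=["compound_id", "smiles", "reason"])


def aggregate_profiles(raw: pd.DataFrame) -> pd.DataFrame:
    """Collapse a well-level profile table to one profile per compound.

    Two steps, applied in order:

    1. *Control subtraction* — per plate, subtract the mean feature vector
       of that plate's neutral-control wells from every treated well.
    2. *Dose-window median* — per compound, keep replicate rows whose dose
       lies within one sample standard deviation of the compound's mean
       dose (inclusive on both ends) and take the feature-wise median.
       Compounds measured at a single dose pass through unchanged.

    Raises
    ------
    ValueError
        If a plate holding treated wells has no control wells.
    """
    for col in RAW_META_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"raw profile table missing column {col!r}")
    feature_cols = [c for c in raw.columns if c not in RAW_META_COLUMNS]
    if not feature_cols:
        raise ValueError("raw profile table has no feature columns")

    is_ctrl = raw["is_control"].astype(bool).to_numpy()
    treated = raw.loc[~is_ctrl]
    controls = raw.loc[is_ctrl]

    ctrl_means = controls.groupby("plate_id")[feature_cols].mean()
    missing = set(treated["plate_id"]) - set(ctrl_means.index)
    if missing:
        raise ValueError(f"plate(s) without control wells: {sorted(missing)}")

    centered = treated[feature_cols].to_numpy(dtype=float) - ctrl_means.loc[
        treated["plate_id"]
    ].to_numpy()
    centered = pd.DataFrame(centered, columns=feature_cols, index=treated.index)
    centered["compound_id"] = treated["compound_id"].astype(str).to_numpy()
    centered["dose"] = treated["dose"].to_numpy(dtype=float)

    profiles = {}
    for cid, grp in centered.groupby("compound_id", sort=True):
        doses = grp["dose"].to_numpy()
        if len(grp) > 1:
            mu, sd = doses.mean(), doses.std(ddof=1)
            keep = (doses >= mu - sd) & (doses <= mu + sd)
        else:
            keep = np.ones(len(grp), dtype=bool)
        profiles[cid] = grp.loc[keep, feature_cols].median(axis=0).to_numpy()
    out = pd.DataFrame.from_dict(profiles, orient="index", columns=feature_cols)
    out.index.name = "compound_id"
    return out


def _abs_corr(X: np.ndarray) -> np.ndarray:
    """|Pearson r| matrix with zero-variance columns correlating 0."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0)
    Z = X - X.mean(axis=0)
    nonzero = sd > 0
    Z[:, nonzero] /= sd[nonzero]
    r = Z.T @ Z / X.shape[0]
    r[~nonzero, :] = 0.0
    r[:, ~nonzero] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.abs(np.clip(r, -1.0, 1.0))


def correlation_prune(X: pd.DataFrame, threshold: float = 0.9) -> list[str]:
    """Greedily drop features until no pair exceeds ``|r| > threshold``.

    While any surviving pair has absolute Pearson correlation strictly
    above the threshold, drop the offending feature with the largest sum of
    absolute correlations to all surviving features; ties drop the later
    column, keeping earlier features.  Correlation with a zero-variance
    feature is defined as 0.  Returns surviving names in original order.
    """
    if len(X) < 2:
        raise ValueError("correlation_prune needs at least 2 rows")
    names = list(X.columns)
    corr = _abs_corr(X.to_numpy())
    alive = np.ones(len(names), dtype=bool)
    while True:
        sub = corr[np.ix_(alive, alive)]
        off = sub - np.eye(sub.shape[0])
        offending = (off > threshold).any(axis=1)
        if not offending.any():
            break
        sums = off.sum(axis=1)
        sums[~offending] = -np.inf  # only features in a violating pair are candidates
        # argmax of (sum, column position): later column wins ties
        best = np.flatnonzero(sums == sums.max())[-1]
        alive[np.flatnonzero(alive)[best]] = False
    return [n for n, a in zip(names, alive) if a]


def select_morph_features(
    X: pd.DataFrame, cfg: FeatureSelectionConfig | None = None
) -> list[str]:
    """Select morphology features on training rows only.

    Applies, in order: blocklist removal, variance floor (population
    variance must exceed ``variance_threshold``), correlation pruning, and
    removal of features whose maximum absolute value exceeds
    ``max_abs_value``.  Returns kept names in original column order.
    """
    cfg = cfg or FeatureSelectionConfig()
    kept = [c for c in X.columns if c not in cfg.blocklist]
    if kept:
        var = X[kept].to_numpy(dtype=float).var(axis=0)
        kept = [c for c, v in zip(kept, var) if v > cfg.variance_threshold]
    if kept:
        kept = correlation_prune(X[kept], cfg.correlation_threshold)
    if kept:
        maxabs = np.abs(X[kept].to_numpy(dtype=float)).max(axis=0)
        kept = [c for c, m in zip(kept, maxabs) if m <= cfg.max_abs_value]
    if not kept:
        raise ValueError(
            "feature selection removed every morphology feature; "
            "relax the variance/correlation/max-abs thresholds"
        )
    return kept


def select_fp_bits(X: pd.DataFrame, threshold: float = 0.05) -> list[str]:
    """Keep fingerprint bits whose Bernoulli variance p(1-p) exceeds
    ``threshold`` (population variance on training rows)."""
    values = X.to_numpy(dtype=float)
    if not np.isin(values, (0, 1)).all():
        raise ValueError("fingerprint matrix must be binary")
    p = values.mean(axis=0)
    var = p * (1.0 - p)
    return [c for c, v in zip(X.columns, var) if v > threshold]
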