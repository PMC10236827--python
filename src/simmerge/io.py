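"""Readers and writers for the tabular formats the pipeline exchanges.

All tables are comma-separated UTF-8 with a header row and ``compound_id``
as the first column.  Profile and fingerprint tables may alternatively be
stored as parquet (selected by the ``.parquet`` extension) for large runs;
the CSV path is the canonical, human-readable one.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

ASSAY_COLUMNS = ("compound_id", "assay_id", "hit_call")


class SchemaError(ValueError):
    """Input table violates the documented schema."""


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)


def read_assay_table(path: str | Path) -> pd.DataFrame:
    """Read a sparse assay hit-call table.

    Expects columns ``compound_id``, ``assay_id``, ``hit_call``; one row
    per measured (compound, assay) pair; ``hit_call`` in {0, 1}.

    Raises
    ------
    SchemaError
        If a required column is missing or a (compound, assay) pair is
        duplicated.
    ValueError
        If ``hit_call`` contains values outside {0, 1}.
    """
    df = _read_table(path)
    missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"assay table missing column(s): {missing}")
    df = df.loc[:, list(ASSAY_COLUMNS)].copy()
    df["compound_id"] = df["compound_id"].astype(str)
    df["assay_id"] = df["assay_id"].astype(str)
    calls = df["hit_call"].to_numpy()
    if not np.isin(calls, (0, 1)).all():
        bad = sorted(set(calls) - {0, 1})
        raise ValueError(f"hit_call values outside {{0,1}}: {bad}")
    df["hit_call"] = df["hit_call"].astype(np.int8)
    dup = df.duplicated(subset=["compound_id", "assay_id"])
    if dup.any():
        pairs = df.loc[dup, ["compound_id", "assay_id"]].values.tolist()
        raise SchemaError(f"duplicate (compound_id, assay_id) pairs: {pairs[:5]}")
    return df.reset_index(drop=True)


def validate_assay_table(df: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`read_assay_table` validation to an in-memory frame."""
    missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"assay table missing column(s): {missing}")
    calls = df["hit_call"].to_numpy()
    if not np.isin(calls, (0, 1)).all():
        raise ValueError("hit_call values outside {0,1}")
    if df.duplicated(subset=["compound_id", "assay_id"]).any():
        raise SchemaError("duplicate (compound_id, assay_id) pairs")
    out = df.loc[:, list(ASSAY_COLUMNS)].copy()
    out["compound_id"] = out["compound_id"].astype(str)
    out["assay_id"] = out["assay_id"].astype(str)
    out["hit_call"] = out["hit_call"].astype(np.int8)
    return out.reset_index(drop=True)


def read_feature_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a compound-by-feature matrix keyed by ``compound_id``.

    Parameters
    ----------
    path
        CSV (or parquet) whose first column is ``compound_id``.
    kind
        ``"fingerprint"`` enforces binary {0, 1} entries; ``"morphology"``
        allows any finite real value.
    """
    if kind not in ("fingerprint", "morphology"):
        raise ValueError(f"kind must be 'fingerprint' or 'morphology', got {kind!r}")
    df = _read_table(path)
    if "compound_id" not in df.columns:
        raise SchemaError("feature table missing 'compound_id' column")
    df = df.set_index(df["compound_id"].astype(str)).drop(columns="compound_id")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("feature table contains non-numeric columns")
    if kind == "fingerprint":
        if not np.isin(values, (0, 1)).all():
            raise ValueError("fingerprint table contains non-binary values")
        df = df.astype(np.uint8)
    else:
        if not np.isfinite(values).all():
            raise ValueError("morphology table contains non-finite values")
        df = df.astype(np.float64)
    if df.index.duplicated().any():
        raise SchemaError("duplicate compound_id rows in feature table")
    return df


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a compound-by-feature matrix (index named compound_id)."""
    path = Path(path)
    out = df.rename_axis("compound_id")
    if path.suffix == ".parquet":
        out.reset_index().to_parquet(path, index=False)
    else:
        out.to_csv(path)


def write_predictions(records: pd.DataFrame, path: str | Path) -> None:
    """Write per-compound prediction records to CSV.

    Values round-trip through :func:`read_predictions` exactly (floats are
    written with full repr precision, which Python parses back bit-for-bit;
    the documented guarantee is 1e-12).
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"output directory does not exist: {path.parent}")
    records.to_csv(path, index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_blocklist(path: str | Path) -> frozenset[str]:
    """Read a feature blocklist: plain text, one feature name per line."""
    names = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            names.append(line)
    return frozenset(names)
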