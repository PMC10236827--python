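"""Per-assay modelling datasets.

For every assay the sparse hit-call table is intersected with both feature
spaces, assays whose minority class is too small are discarded, the
majority class is randomly undersampled (without replacement) down to at
most ``max_majority_ratio`` times the minority class, and the result is
split 80/20 with stratification on the hit call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .config import RunConfig


@dataclass
class AssayDataset:
    """Row-aligned labels and feature matrices for one assay."""

    assay_id: str
    compound_ids: list[str]
    y: np.ndarray
    X_struct: pd.DataFrame
    X_morph: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.compound_ids)
        if not (len(self.y) == len(self.X_struct) == len(self.X_morph) == n):
            raise ValueError("misaligned rows across y/X_struct/X_morph")


@dataclass
class SplitIndices:
    """Positional train/test indices partitioning an AssayDataset."""

    train_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class BuildReport:
    """Retained and discarded assays with reasons and final class counts."""

    retained: dict[str, dict] = field(default_factory=dict)
    discarded: dict[str, str] = field(default_factory=dict)


def build_assay_datasets(
    assays: pd.DataFrame,
    fps: pd.DataFrame,
    morph: pd.DataFrame,
    cfg: RunConfig,
) -> tuple[dict[str, AssayDataset], BuildReport]:
    """Assemble one :class:`AssayDataset` per retained assay.

    Per assay: keep compounds present in both feature matrices; discard the
    assay if only one class remains or the minority class has fewer than
    ``cfg.min_minority`` compounds; undersample the majority class (the
    larger class, whichever label it carries) without replacement down to
    ``cfg.max_majority_ratio`` times the minority count.  Minority
    compounds are never removed.  Sampling is seeded per assay from
    ``cfg.seed`` so a rebuild is reproducible.
    """
    common = fps.index.intersection(morph.index)
    datasets: dict[str, AssayDataset] = {}
    report = BuildReport()
    for assay_id, grp in assays.groupby("assay_id", sort=True):
        grp = grp[grp["compound_id"].isin(common)]
        counts = grp["hit_call"].value_counts()
        if len(counts) < 2:
            report.discarded[assay_id] = "single class after feature intersection"
            continue
        minority_label = counts.idxmin()
        n_min, n_maj = counts.min(), counts.max()
        if n_min < cfg.min_minority:
            report.discarded[assay_id] = (
                f"minority class has {n_min} compounds < min_minority={cfg.min_minority}"
            )
            continue
        cap = int(np.floor(cfg.max_majority_ratio * n_min))
        minority = grp[grp["hit_call"] == minority_label]
        majority = grp[grp["hit_call"] != minority_label]
        if n_maj > cap:
            rng = np.random.default_rng(cfg.stage_seed(f"undersample:{assay_id}"))
            majority = majority.sort_values("compound_id")
            keep = rng.choice(len(majority), size=cap, replace=False)
            majority = majority.iloc[np.sort(keep)]
        kept = pd.concat([minority, majority]).sort_values("compound_id")
        ids = kept["compound_id"].tolist()
        datasets[assay_id] = AssayDataset(
            assay_id=assay_id,
            compound_ids=ids,
            y=kept["hit_call"].to_numpy(dtype=np.int8),
            X_struct=fps.loc[ids],
            X_morph=morph.loc[ids],
        )
        report.retained[assay_id] = {
            "n_minority": int(min(len(minority), len(majority))),
            "n_majority": int(max(len(minority), len(majority))),
            "minority_label": int(minority_label),
        }
    return datasets, report


def stratified_split(ds: AssayDataset, cfg: RunConfig) -> SplitIndices:
    """Stratified train/test split of one assay dataset.

    ``cfg.test_fraction`` of each class (to rounding) goes to the test
    part; deterministic under a fixed ``cfg.seed``.
    """
    counts = np.bincount(ds.y)
    if (counts[counts > 0] < 2).any():
        raise ValueError("each class needs at least 2 members to stratify")
    idx = np.arange(len(ds.y))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=cfg.test_fraction,
        stratify=ds.y,
        random_state=cfg.stage_seed(f"split:{ds.assay_id}"),
        shuffle=True,
    )
    return SplitIndices(train_idx=np.sort(train_idx), test_idx=np.sort(test_idx))
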