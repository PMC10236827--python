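"""Desk-scale synthetic benchmark harness.

Runs the full workflow over seeded synthetic assays and collects held-out
AUCs, so the synergy behaviour of the similarity-based merger (and the
signal-mode contract of the generator) can be measured reproducibly
without any external data.  Problem sizes follow the generator defaults
(400 compounds, 256 bits, 60 morphology features); the single-candidate
hyperparameter space keeps a 10-seed benchmark tractable on one core.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import RunConfig
from .dataset import build_assay_datasets, stratified_split
from .evaluation import auc_score
from .featurization import FeatureSelectionConfig, select_fp_bits, select_morph_features
from .learner import HyperparameterSpace, compact_space, fit_final_model
from .pipeline import run_assay
from .synthetic import SyntheticConfig, generate_assay


def _dataset_for(cfg: SyntheticConfig, run_cfg: RunConfig):
    fps, morph, assay = generate_assay(cfg)
    datasets, report = build_assay_datasets(assay, fps, morph, run_cfg)
    if not datasets:
        raise RuntimeError(f"synthetic assay discarded: {report.discarded}")
    return next(iter(datasets.values()))


def run_complementary_benchmark(
    n_seeds: int = 10,
    base_seed: int = 0,
    space: HyperparameterSpace | None = None,
) -> pd.DataFrame:
    """Held-out AUC of all five models over seeded complementary assays.

    Returns one row per (seed, model) with the held-out AUC; the merger's
    synergy claim is a statement about the per-model means of this table.
    """
    space = space or compact_space()
    rows = []
    for i in range(n_seeds):
        seed = (base_seed + i) % (2**31 - 1)
        cfg = SyntheticConfig(signal_mode="complementary", seed=seed)
        run_cfg = RunConfig(seed=seed)
        ds = _dataset_for(cfg, run_cfg)
        result = run_assay(ds, run_cfg, space=space)
        for _, row in result.metrics.iterrows():
            rows.append({"seed": seed, "model": row["model"], "auc": row["auc"]})
    return pd.DataFrame(rows)


def run_mode_dominance(
    mode: str,
    n_seeds: int = 10,
    base_seed: int = 0,
    space: HyperparameterSpace | None = None,
) -> pd.DataFrame:
    """Held-out AUC of the two individual models under one signal mode.

    Fits only the two calibrated base models (no stacking), which is all
    the dominance comparison needs.  Returns one row per seed with
    ``auc_struct`` and ``auc_morph``.
    """
    space = space or compact_space()
    selection = FeatureSelectionConfig()
    rows = []
    for i in range(n_seeds):
        seed = (base_seed + i) % (2**31 - 1)
        cfg = SyntheticConfig(signal_mode=mode, seed=seed)
        run_cfg = RunConfig(seed=seed)
        ds = _dataset_for(cfg, run_cfg)
        split = stratified_split(ds, run_cfg)
        tr, te = split.train_idx, split.test_idx
        bits = select_fp_bits(ds.X_struct.iloc[tr], selection.fp_variance_threshold)
        morph_names = select_morph_features(ds.X_morph.iloc[tr], selection)
        aucs = {}
        for tag, X in (("struct", ds.X_struct[bits]), ("morph", ds.X_morph[morph_names])):
            model = fit_final_model(X.iloc[tr], ds.y[tr], tag, run_cfg, space,
                                    ds.assay_id)
            aucs[tag] = auc_score(ds.y[te], model.predict_scaled(X.iloc[te]))
        rows.append({"seed": seed, "auc_struct": aucs["struct"],
                     "auc_morph": aucs["morph"]})
    return pd.DataFrame(rows)
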