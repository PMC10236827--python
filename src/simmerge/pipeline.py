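"""End-to-end orchestration for one or more assays.

For each retained assay: stratified 80/20 split; feature selection fitted
on the training split only; fivefold nested cross-validation producing
out-of-fold stacking features; final calibrated base models on the full
training split; the three fusion schemes fitted on the out-of-fold
features; held-out predictions and metrics for all five models
(structural, morphology, soft-vote, hierarchical, similarity merger).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .dataset import AssayDataset, SplitIndices, build_assay_datasets, stratified_split
from .evaluation import compute_metrics
from .featurization import FeatureSelectionConfig, select_fp_bits, select_morph_features
from .learner import (
    CalibratedModel,
    HyperparameterSpace,
    default_space,
    fit_final_model,
    run_nested_cv,
)
from .mergers import (
    MergerConfig,
    fit_hierarchical,
    fit_similarity_merger,
    predict_hierarchical,
    predict_merger,
    soft_vote,
)
from .similarity import SimilarityConfig, score_compound_set

MODEL_TAGS = ["struct", "morph", "soft_vote", "hierarchical", "merger"]


@dataclass
class AssayResult:
    """Everything the pipeline produced for one assay."""

    assay_id: str
    predictions: pd.DataFrame  # held-out compounds, one row each
    oof: pd.DataFrame  # out-of-fold training features
    metrics: pd.DataFrame  # one row per model tag
    merger_coefficients: dict[str, float] = field(default_factory=dict)
    merger_intercept: float = 0.0
    selected_bits: list[str] = field(default_factory=list)
    selected_morph: list[str] = field(default_factory=list)


def run_assay(
    ds: AssayDataset,
    cfg: RunConfig,
    space: HyperparameterSpace | None = None,
    selection: FeatureSelectionConfig | None = None,
    sim_cfg: SimilarityConfig | None = None,
    merger_cfg: MergerConfig | None = None,
    split: SplitIndices | None = None,
) -> AssayResult:
    """Run the full modelling workflow for one assay dataset."""
    space = space or default_space()
    selection = selection or FeatureSelectionConfig()
    sim_cfg = sim_cfg or SimilarityConfig()
    merger_cfg = merger_cfg or MergerConfig()

    split = split or stratified_split(ds, cfg)
    tr, te = split.train_idx, split.test_idx
    y = ds.y

    # feature selection never sees held-out compounds
    bits = select_fp_bits(ds.X_struct.iloc[tr], selection.fp_variance_threshold)
    morph_names = select_morph_features(ds.X_morph.iloc[tr], selection)
    Xs = ds.X_struct[bits]
    Xm = ds.X_morph[morph_names]

    train_ids = [ds.compound_ids[i] for i in tr]
    oof = run_nested_cv(
        Xs.iloc[tr], Xm.iloc[tr], y[tr], train_ids, cfg,
        space=space, sim_cfg=sim_cfg, assay_id=ds.assay_id,
    )

    final_struct = fit_final_model(Xs.iloc[tr], y[tr], "struct", cfg, space, ds.assay_id)
    final_morph = fit_final_model(Xm.iloc[tr], y[tr], "morph", cfg, space, ds.assay_id)

    p_struct = final_struct.predict_scaled(Xs.iloc[te])
    p_morph = final_morph.predict_scaled(Xm.iloc[te])

    actives = tr[y[tr] == 1]
    sims = score_compound_set(
        Xs.iloc[te].to_numpy(), Xm.iloc[te].to_numpy(),
        Xs.iloc[actives].to_numpy(), Xm.iloc[actives].to_numpy(), sim_cfg,
    )

    held_out = pd.DataFrame({
        "compound_id": [ds.compound_ids[i] for i in te],
        "assay_id": ds.assay_id,
        "y": y[te],
        "p_struct_scaled": p_struct,
        "p_morph_scaled": p_morph,
        "s_struct": sims["s_struct"].to_numpy(),
        "s_morph": sims["s_morph"].to_numpy(),
    })

    p_soft, call_soft = soft_vote(held_out["p_struct_scaled"].to_numpy(),
                                  held_out["p_morph_scaled"].to_numpy())
    hier = fit_hierarchical(oof, cfg.stage_seed(f"hier:{ds.assay_id}"), cfg.n_inner_folds)
    p_hier, call_hier = predict_hierarchical(hier, held_out)
    merger = fit_similarity_merger(oof, merger_cfg)
    p_merge, call_merge = predict_merger(merger, held_out)

    held_out["call_struct"] = (held_out["p_struct_scaled"] >= 0.5).astype(int)
    held_out["call_morph"] = (held_out["p_morph_scaled"] >= 0.5).astype(int)
    held_out["p_soft_vote"] = p_soft
    held_out["call_soft_vote"] = call_soft
    held_out["p_hierarchical"] = p_hier
    held_out["call_hierarchical"] = call_hier
    held_out["p_merger"] = p_merge
    held_out["call_merger"] = call_merge

    prob_cols = {"struct": "p_struct_scaled", "morph": "p_morph_scaled",
                 "soft_vote": "p_soft_vote", "hierarchical": "p_hierarchical",
                 "merger": "p_merger"}
    rows = []
    for tag in MODEL_TAGS:
        m = compute_metrics(
            held_out["y"].to_numpy(),
            held_out[f"call_{tag}"].to_numpy(),
            held_out[prob_cols[tag]].to_numpy(),
        )
        rows.append({"assay_id": ds.assay_id, "model": tag, **m})
    metrics = pd.DataFrame(rows)

    return AssayResult(
        assay_id=ds.assay_id,
        predictions=held_out,
        oof=oof,
        metrics=metrics,
        merger_coefficients=merger.coefficients,
        merger_intercept=merger.intercept,
        selected_bits=bits,
        selected_morph=morph_names,
    )


def run_pipeline(
    assays: pd.DataFrame,
    fps: pd.DataFrame,
    morph: pd.DataFrame,
    cfg: RunConfig,
    space: HyperparameterSpace | None = None,
    selection: FeatureSelectionConfig | None = None,
    sim_cfg: SimilarityConfig | None = None,
    merger_cfg: MergerConfig | None = None,
) -> tuple[list[AssayResult], dict]:
    """Build datasets for every assay and run the per-assay workflow.

    Returns the per-assay results and a manifest of retained/discarded
    assays with final class counts.
    """
    datasets, report = build_assay_datasets(assays, fps, morph, cfg)
    results = [
        run_assay(ds, cfg, space=space, selection=selection,
                  sim_cfg=sim_cfg, merger_cfg=merger_cfg)
        for ds in datasets.values()
    ]
    manifest = {"retained": report.retained, "discarded": report.discarded,
                "seed": cfg.seed}
    return results, manifest
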