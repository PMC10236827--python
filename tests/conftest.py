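import numpy as np
import pandas as pd
import pytest

from simmerge import RunConfig, SyntheticConfig, generate_assay


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_synthetic():
    """A desk-scale complementary-mode assay small enough for fast tests."""
    cfg = SyntheticConfig(
        n_compounds=160, n_bits=128, n_morph_features=30, n_scaffolds=8,
        active_fraction=0.25, signal_mode="complementary", seed=7,
    )
    fps, morph, assay = generate_assay(cfg)
    return fps, morph, assay


@pytest.fixture
def small_run_config():
    return RunConfig(seed=7, min_minority=10)


def make_assay_frame(n_active: int, n_inactive: int, assay_id: str = "A1") -> pd.DataFrame:
    ids = [f"c{i:04d}" for i in range(n_active + n_inactive)]
    return pd.DataFrame({
        "compound_id": ids,
        "assay_id": assay_id,
        "hit_call": [1] * n_active + [0] * n_inactive,
    })


def make_feature_frames(ids, n_bits=16, n_morph=8, seed=0):
    rng = np.random.default_rng(seed)
    fps = pd.DataFrame(
        rng.integers(0, 2, size=(len(ids), n_bits), dtype=np.uint8),
        index=pd.Index(ids, name="compound_id"),
        columns=[f"fp_{i:04d}" for i in range(n_bits)],
    )
    morph = pd.DataFrame(
        rng.normal(size=(len(ids), n_morph)),
        index=pd.Index(ids, name="compound_id"),
        columns=[f"m_{i:03d}" for i in range(n_morph)],
    )
    return fps, morph
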