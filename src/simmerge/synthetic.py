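"""Seeded synthetic benchmark datasets.

The generator emulates the statistical structure of the real inputs — a
sparse binary fingerprint matrix with scaffold clusters, a continuous
morphological profile matrix with an activity-correlated signature, and a
binary hit-call table — without any chemistry.  Compounds are noisy copies
of scaffold prototype bit vectors; active compounds may carry a unit-norm
morphological signature on top of Gaussian noise.  Three signal modes
control which feature space carries the activity signal:

* ``structure`` — activity is determined by scaffold membership; the
  morphology matrix is pure noise;
* ``morphology`` — activity is assigned independently of scaffold and the
  signature is present in morphology only;
* ``complementary`` — half the actives are signalled only in structure
  (they occupy scaffolds of their own), half only in morphology, so
  neither single space can recover all actives but a fusion can.

All outputs are deterministic functions of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SIGNAL_MODES = ("structure", "morphology", "complementary")
SCAFFOLD_BIT_PROBABILITY = 0.1  # sparse, fingerprint-like prototypes


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic assay generator.

    Defaults define a desk-scale benchmark: 400 compounds over 10
    scaffolds, 256 fingerprint bits, 60 morphology features, a quarter of
    compounds active, 2% bit-flip noise and unit-signature morphology with
    noise sd 0.5.
    """

    n_compounds: int = 400
    n_bits: int = 256
    n_morph_features: int = 60
    n_scaffolds: int = 10
    active_fraction: float = 0.25
    signal_mode: str = "complementary"
    bit_flip_noise: float = 0.02
    morph_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.active_fraction < 1.0:
            raise ValueError("active_fraction must lie in (0, 1)")
        if self.signal_mode not in SIGNAL_MODES:
            raise ValueError(f"signal_mode must be one of {SIGNAL_MODES}")
        if not 0.0 <= self.bit_flip_noise <= 1.0:
            raise ValueError("bit_flip_noise must lie in [0, 1]")
        if self.morph_noise_sd < 0:
            raise ValueError("morph_noise_sd must be >= 0")
        if self.n_scaffolds > self.n_compounds:
            raise ValueError("n_scaffolds cannot exceed n_compounds")
        if self.n_scaffolds < 2:
            raise ValueError("need at least 2 scaffolds")


def _compound_ids(n: int) -> list[str]:
    return [f"C{i:05d}" for i in range(n)]


def generate_assay(
    cfg: SyntheticConfig, assay_id: str = "synthetic_assay"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """One synthetic assay: (fingerprints, morphology, hit-call table).

    Fingerprint rows are scaffold prototypes with independent per-bit flip
    noise; morphology rows are Gaussian noise plus, for morphology-
    signalled actives, a fixed unit-norm signature.  Labels follow the
    configured signal mode.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_compounds
    n_act = int(round(cfg.active_fraction * n))
    ids = _compound_ids(n)

    prototypes = (rng.random((cfg.n_scaffolds, cfg.n_bits)) < SCAFFOLD_BIT_PROBABILITY
                  ).astype(np.uint8)

    y = np.zeros(n, dtype=np.int8)
    scaffold = np.empty(n, dtype=int)
    morph_signal = np.zeros(n, dtype=bool)

    if cfg.signal_mode == "structure":
        # activity == membership of designated active scaffolds
        k_act = max(1, round(cfg.active_fraction * cfg.n_scaffolds))
        y[:n_act] = 1
        scaffold[:n_act] = np.arange(n_act) % k_act
        scaffold[n_act:] = k_act + np.arange(n - n_act) % (cfg.n_scaffolds - k_act)
    elif cfg.signal_mode == "morphology":
        # scaffolds independent of labels; signature marks the actives
        y[rng.choice(n, size=n_act, replace=False)] = 1
        scaffold = np.arange(n) % cfg.n_scaffolds
        morph_signal = y == 1
    else:  # complementary
        n_struct_act = n_act // 2
        k_act = max(1, round(n_struct_act / n * cfg.n_scaffolds))
        if cfg.n_scaffolds - k_act < 1:
            raise ValueError("too few scaffolds for complementary mode")
        y[:n_act] = 1
        # structure-signalled actives own their scaffolds exclusively
        scaffold[:n_struct_act] = np.arange(n_struct_act) % k_act
        rest = n - n_struct_act
        scaffold[n_struct_act:] = k_act + np.arange(rest) % (cfg.n_scaffolds - k_act)
        morph_signal[n_struct_act:n_act] = True

    perm = rng.permutation(n)
    y, scaffold, morph_signal = y[perm], scaffold[perm], morph_signal[perm]

    flips = rng.random((n, cfg.n_bits)) < cfg.bit_flip_noise
    fps = np.where(flips, 1 - prototypes[scaffold], prototypes[scaffold]).astype(np.uint8)

    # Compact signature: a random sixth of the features respond with unit
    # magnitude (random sign), mimicking an organelle-specific phenotype
    # rather than a diffuse shift over all features.
    n_resp = max(5, cfg.n_morph_features // 6)
    signature = np.zeros(cfg.n_morph_features)
    responding = rng.choice(cfg.n_morph_features, size=n_resp, replace=False)
    signature[responding] = rng.choice([-1.0, 1.0], size=n_resp)
    morph = rng.normal(scale=cfg.morph_noise_sd, size=(n, cfg.n_morph_features))
    morph[morph_signal] += signature

    fp_df = pd.DataFrame(fps, index=pd.Index(ids, name="compound_id"),
                         columns=[f"fp_{i:04d}" for i in range(cfg.n_bits)])
    morph_df = pd.DataFrame(morph, index=pd.Index(ids, name="compound_id"),
                            columns=[f"m_{i:03d}" for i in range(cfg.n_morph_features)])
    assay_df = pd.DataFrame({
        "compound_id": ids,
        "assay_id": assay_id,
        "hit_call": y.astype(np.int8),
    })
    return fp_df, morph_df, assay_df


def generate_raw_profiles(
    cfg: SyntheticConfig,
    plates: int = 2,
    doses: list[float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Well-level profile table with plate effects and dose replicates.

    Each compound sits on one plate (round-robin) with one treated well per
    dose; every plate carries control wells.  An additive per-plate offset
    is applied to treated and control wells alike, so control subtraction
    cancels it; with ``morph_noise_sd = 0`` the aggregated profile equals
    the latent per-compound profile exactly.

    Returns ``(raw_table, latent_profiles)``.
    """
    if doses is None:
        doses = [1.0, 3.0, 10.0]
    if len(doses) == 0:
        raise ValueError("dose list must be non-empty")
    if plates < 1:
        raise ValueError("need at least one plate")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_compounds
    ids = _compound_ids(n)
    feature_cols = [f"m_{i:03d}" for i in range(cfg.n_morph_features)]

    latent = rng.normal(size=(n, cfg.n_morph_features))
    plate_offsets = rng.normal(scale=2.0, size=(plates, cfg.n_morph_features))
    plate_of = np.arange(n) % plates

    rows = []
    for i, cid in enumerate(ids):
        for dose in doses:
            noise = rng.normal(scale=cfg.morph_noise_sd, size=cfg.n_morph_features)
            values = latent[i] + plate_offsets[plate_of[i]] + noise
            rows.append({"compound_id": cid, "plate_id": f"P{plate_of[i]:02d}",
                         "dose": dose, "is_control": 0,
                         **dict(zip(feature_cols, values))})
    for p in range(plates):
        for w in range(4):  # four neutral-control wells per plate
            noise = rng.normal(scale=cfg.morph_noise_sd, size=cfg.n_morph_features)
            values = plate_offsets[p] + noise
            rows.append({"compound_id": f"control_{p}_{w}", "plate_id": f"P{p:02d}",
                         "dose": 0.0, "is_control": 1,
                         **dict(zip(feature_cols, values))})
    raw = pd.DataFrame(rows)
    latent_df = pd.DataFrame(latent, index=pd.Index(ids, name="compound_id"),
                             columns=feature_cols)
    return raw, latent_df
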