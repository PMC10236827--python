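"""Run configuration and deterministic seed derivation.

A single integer seed in :class:`RunConfig` drives every stochastic stage
of the pipeline (splitting, undersampling, hyperparameter search, model
fitting).  Each stage derives its own child seed from the run seed plus a
stage name, so stages are decoupled: changing the number of tuning
iterations, say, never perturbs the train/test split.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path


class ConfigError(ValueError):
    """A RunConfig field is outside its valid range."""


@dataclass
class RunConfig:
    """Pipeline-wide settings.

    Parameters
    ----------
    seed
        Master random seed; all stage seeds derive from it.
    test_fraction
        Fraction of each assay dataset held out for final evaluation
        (default 0.2, i.e. an 80/20 split).
    n_outer_folds, n_inner_folds
        Fold counts for the nested cross-validation (default fivefold in
        both layers).
    min_minority
        Assays whose minority class has fewer compounds than this are
        discarded (default 100).
    max_majority_ratio
        Majority class is randomly undersampled (without replacement) down
        to at most this multiple of the minority class (default 3.0).
    output_dir
        Where CLI subcommands write their artifacts.
    """

    seed: int = 0
    test_fraction: float = 0.2
    n_outer_folds: int = 5
    n_inner_folds: int = 5
    min_minority: int = 100
    max_majority_ratio: float = 3.0
    output_dir: Path = field(default_factory=lambda: Path("."))

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigError(
                f"test_fraction must lie in (0, 1), got {self.test_fraction}"
            )
        if self.n_outer_folds < 2:
            raise ConfigError(f"n_outer_folds must be >= 2, got {self.n_outer_folds}")
        if self.n_inner_folds < 2:
            raise ConfigError(f"n_inner_folds must be >= 2, got {self.n_inner_folds}")
        if self.min_minority < 1:
            raise ConfigError(f"min_minority must be >= 1, got {self.min_minority}")
        if self.max_majority_ratio < 1.0:
            raise ConfigError(
                f"max_majority_ratio must be >= 1, got {self.max_majority_ratio}"
            )
        self.output_dir = Path(self.output_dir)

    def stage_seed(self, stage: str) -> int:
        """Deterministic child seed for a named pipeline stage.

        The same (seed, stage) pair always yields the same value, and the
        value fits in a signed 32-bit integer as required by scikit-learn
        ``random_state`` arguments.
        """
        return (self.seed * 1_000_003 + zlib.crc32(stage.encode("utf-8"))) % (2**31 - 1)
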