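import numpy as np
import pandas as pd
import pytest

from simmerge import (
    FeatureSelectionConfig,
    aggregate_profiles,
    compute_fingerprints,
    correlation_prune,
    select_fp_bits,
    select_morph_features,
    tanimoto,
)


class TestFingerprints:
    def test_identical_smiles_identical_rows(self):
        matrix, rejects = compute_fingerprints({"a": "c1ccccc1", "b": "c1ccccc1"})
        assert rejects.empty
        np.testing.assert_array_equal(matrix.loc["a"], matrix.loc["b"])
        assert matrix.shape == (2, 2048)
        assert set(np.unique(matrix.to_numpy())) <= {0, 1}

    def test_unparseable_smiles_collected(self):
        matrix, rejects = compute_fingerprints({"ok": "CCO", "bad": "not-a-smiles"})
        assert list(matrix.index) == ["ok"]
        assert rejects["compound_id"].tolist() == ["bad"]

    def test_different_structures_not_identical(self):
        matrix, _ = compute_fingerprints({"benzene": "c1ccccc1", "ethanol": "CCO"})
        t = tanimoto(matrix.loc["benzene"].to_numpy(), matrix.loc["ethanol"].to_numpy())
        assert t < 1.0


def _raw_frame(rows):
    return pd.DataFrame(rows)


class TestAggregateProfiles:
    def test_control_subtraction(self):
        raw = _raw_frame([
            {"compound_id": "c1", "plate_id": "P1", "dose": 1.0, "is_control": 0, "f0": 2.0},
            {"compound_id": "ctl", "plate_id": "P1", "dose": 0.0, "is_control": 1, "f0": 0.5},
        ])
        out = aggregate_profiles(raw)
        assert out.loc["c1", "f0"] == pytest.approx(1.5)

    def test_dose_window_median(self):
        # doses {1,3,10}: mean 4.667, sample sd 4.726 -> window keeps {1,3}
        raw = _raw_frame([
            {"compound_id": "c1", "plate_id": "P1", "dose": 1.0, "is_control": 0, "f0": 1.0},
            {"compound_id": "c1", "plate_id": "P1", "dose": 3.0, "is_control": 0, "f0": 3.0},
            {"compound_id": "c1", "plate_id": "P1", "dose": 10.0, "is_control": 0, "f0": 100.0},
            {"compound_id": "ctl", "plate_id": "P1", "dose": 0.0, "is_control": 1, "f0": 0.0},
        ])
        out = aggregate_profiles(raw)
        assert out.loc["c1", "f0"] == pytest.approx(2.0)

    def test_single_dose_median(self):
        raw = _raw_frame(
            [{"compound_id": "c1", "plate_id": "P1", "dose": 5.0, "is_control": 0, "f0": v}
             for v in (1.0, 2.0, 9.0)]
            + [{"compound_id": "ctl", "plate_id": "P1", "dose": 0.0, "is_control": 1, "f0": 0.0}]
        )
        assert aggregate_profiles(raw).loc["c1", "f0"] == pytest.approx(2.0)

    def test_plate_without_controls_named(self):
        raw = _raw_frame([
            {"compound_id": "c1", "plate_id": "P9", "dose": 1.0, "is_control": 0, "f0": 2.0},
        ])
        with pytest.raises(ValueError, match="P9"):
            aggregate_profiles(raw)

    def test_row_order_invariance(self, rng):
        rows = []
        for i in range(6):
            for dose in (1.0, 3.0):
                rows.append({"compound_id": f"c{i}", "plate_id": f"P{i % 2}",
                             "dose": dose, "is_control": 0,
                             "f0": rng.normal(), "f1": rng.normal()})
        for p in range(2):
            rows.append({"compound_id": f"ctl{p}", "plate_id": f"P{p}",
                         "dose": 0.0, "is_control": 1,
                         "f0": rng.normal(), "f1": rng.normal()})
        raw = _raw_frame(rows)
        shuffled = raw.sample(frac=1.0, random_state=3).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            aggregate_profiles(raw), aggregate_profiles(shuffled),
            check_exact=False, rtol=1e-12, atol=1e-12,
        )


class TestCorrelationPrune:
    def test_duplicate_feature_dropped_earlier_kept(self, rng):
        x = rng.normal(size=100)
        X = pd.DataFrame({"f1": x, "f2": x, "f3": rng.normal(size=100)})
        kept = correlation_prune(X, threshold=0.9)
        assert kept == ["f1", "f3"]

    def test_no_offending_pair_is_identity(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 5)), columns=list("abcde"))
        assert correlation_prune(X, threshold=0.9) == list("abcde")

    def test_four_identical_features_leave_one(self, rng):
        x = rng.normal(size=50)
        X = pd.DataFrame({f"f{i}": x for i in range(4)})
        assert correlation_prune(X, threshold=0.9) == ["f0"]

    def test_zero_variance_feature_never_nan(self, rng):
        X = pd.DataFrame({"const": np.full(30, 7.0), "x": rng.normal(size=30)})
        assert correlation_prune(X, threshold=0.9) == ["const", "x"]

    @pytest.mark.parametrize("seed", range(5))
    def test_no_surviving_pair_exceeds_threshold(self, seed):
        # independent exhaustive pair scan over the survivors
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(60, 4))
        mix = base @ rng.normal(size=(4, 12)) + 0.3 * rng.normal(size=(60, 12))
        X = pd.DataFrame(mix, columns=[f"f{i}" for i in range(12)])
        kept = correlation_prune(X, threshold=0.9)
        assert kept
        sub = X[kept].to_numpy()
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                r = np.corrcoef(sub[:, i], sub[:, j])[0, 1]
                assert abs(r) <= 0.9 + 1e-12


class TestSelectMorphFeatures:
    def _frame(self, rng, extra=None):
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=["a", "b", "c", "d"])
        if extra:
            for name, col in extra.items():
                X[name] = col
        return X

    def test_constant_feature_removed(self, rng):
        X = self._frame(rng, {"const": np.full(50, 7.0)})
        kept = select_morph_features(X)
        assert "const" not in kept

    def test_max_abs_violator_removed(self, rng):
        col = rng.uniform(-1, 1, 50)
        col[3] = 20.0
        X = self._frame(rng, {"spike": col})
        assert "spike" not in select_morph_features(X)

    def test_blocklisted_removed_first(self, rng):
        X = self._frame(rng)
        cfg = FeatureSelectionConfig(blocklist=frozenset({"a"}))
        assert "a" not in select_morph_features(X, cfg)

    def test_idempotent(self, rng):
        base = rng.normal(size=(80, 3))
        X = pd.DataFrame(
            np.column_stack([base, base[:, 0] + 0.01 * rng.normal(size=80),
                             np.full(80, 1.0)]),
            columns=["a", "b", "c", "dup_a", "const"],
        )
        kept = select_morph_features(X)
        assert select_morph_features(X[kept]) == kept

    def test_everything_removed_is_an_error(self):
        X = pd.DataFrame({"a": np.full(20, 1.0), "b": np.full(20, 2.0)})
        with pytest.raises(ValueError, match="relax"):
            select_morph_features(X)


class TestSelectFpBits:
    def test_bernoulli_variance_rule(self):
        col_rare = np.zeros(100, dtype=np.uint8)
        col_rare[0] = 1  # p = 0.01 -> var 0.0099 < 0.05
        col_balanced = np.zeros(100, dtype=np.uint8)
        col_balanced[:50] = 1  # p = 0.5 -> var 0.25
        X = pd.DataFrame({"rare": col_rare, "balanced": col_balanced,
                          "zero": np.zeros(100, dtype=np.uint8)})
        assert select_fp_bits(X, threshold=0.05) == ["balanced"]

    def test_non_binary_rejected(self):
        X = pd.DataFrame({"a": [0.5, 1.0]})
        with pytest.raises(ValueError, match="binary"):
            select_fp_bits(X)
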