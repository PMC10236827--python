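import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from simmerge import (
    HyperparameterSpace,
    RunConfig,
    fit_final_model,
    rescale_probability,
    run_nested_cv,
    tune_classifier,
    youden_threshold,
)
from simmerge.learner import compact_space


def brute_force_youden(y, p):
    """Independent exhaustive scan over all candidate thresholds."""
    best_t, best_j = None, -np.inf
    for t in np.unique(p):
        calls = p >= t
        tpr = calls[y == 1].mean()
        fpr = calls[y == 0].mean()
        j = tpr - fpr
        if j > best_j or (j == best_j and t < best_t):
            best_t, best_j = t, j
    return min(max(best_t, 1e-6), 1 - 1e-6), best_j


class TestYoudenThreshold:
    def test_separated_classes(self):
        y = np.array([1, 1, 0, 0])
        p = np.array([0.8, 0.9, 0.1, 0.2])
        cal = youden_threshold(y, p)
        assert cal.threshold == 0.8
        assert cal.j == 1.0

    def test_tie_takes_smallest_threshold(self):
        cal = youden_threshold(np.array([1, 0, 1, 0]),
                               np.array([0.9, 0.6, 0.55, 0.2]))
        assert cal.threshold == 0.55
        assert cal.j == pytest.approx(0.5)

    def test_constant_probability(self):
        cal = youden_threshold(np.array([1, 0]), np.array([0.3, 0.3]))
        assert cal.threshold == pytest.approx(0.3)
        assert cal.j == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            youden_threshold(np.ones(4), np.linspace(0.1, 0.9, 4))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_bruteforce_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 60)
        y = np.zeros(n, dtype=int)
        y[: rng.integers(1, n - 1) + 1] = 1
        rng.shuffle(y)
        if y.sum() in (0, n):
            y[0], y[-1] = 1, 0
        # quantized probabilities force ties between candidates
        p = np.round(rng.random(n), 2)
        cal = youden_threshold(y, p)
        t_ref, j_ref = brute_force_youden(y, p)
        assert cal.threshold == t_ref
        assert cal.j == pytest.approx(j_ref)


class TestRescaleProbability:
    def test_threshold_maps_to_half_exactly(self):
        for t in (0.1, 0.37, 0.5, 0.93):
            assert rescale_probability(t, t) == 0.5

    def test_endpoints_fixed(self):
        assert rescale_probability(0.0, 0.3) == 0.0
        assert rescale_probability(1.0, 0.3) == 1.0

    def test_linear_below_threshold(self):
        assert rescale_probability(0.2, 0.4) == pytest.approx(0.25)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError, match="threshold"):
            rescale_probability(0.5, 1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_monotone_and_classification_preserving(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.uniform(0.05, 0.95)
        p = np.sort(rng.random(30))
        scaled = rescale_probability(p, t)
        assert (np.diff(scaled) >= 0).all()
        strict = np.diff(p) > 0
        assert (np.diff(scaled)[strict] > 0).all()
        np.testing.assert_array_equal(p >= t, scaled >= 0.5)


def _separable_data(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(size=(n, 5))
    X[:, 0] = 10.0 * y + 0.1 * rng.normal(size=n)  # wide-margin separation
    return X, y


class TestTuneClassifier:
    def test_single_candidate_returned(self):
        space = HyperparameterSpace(params={"n_estimators": [50]}, n_iter=5)
        X, y = _separable_data()
        assert tune_classifier(X, y, space, 3, seed=1) == {"n_estimators": 50}

    def test_deterministic_under_seed(self):
        space = HyperparameterSpace(
            params={"n_estimators": [20, 50], "min_samples_leaf": [1, 3]}, n_iter=3
        )
        X, y = _separable_data()
        a = tune_classifier(X, y, space, 3, seed=11)
        b = tune_classifier(X, y, space, 3, seed=11)
        assert a == b

    def test_separable_data_scores_perfectly(self):
        from sklearn.metrics import roc_auc_score
        from sklearn.model_selection import cross_val_predict

        from simmerge.learner import make_classifier

        X, y = _separable_data(seed=5)
        space = HyperparameterSpace(params={"n_estimators": [30, 60]}, n_iter=2)
        params = tune_classifier(X, y, space, 3, seed=2)
        p = cross_val_predict(make_classifier(params, 2), X, y, cv=3,
                              method="predict_proba")[:, 1]
        assert roc_auc_score(y, p) == 1.0

    def test_degenerate_feature_matrix(self):
        with pytest.raises(ValueError, match="feature"):
            tune_classifier(np.empty((10, 0)), np.array([0, 1] * 5),
                            compact_space(), 3, seed=0)


def _toy_nested_inputs(n=100, seed=3):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    Xs = (rng.random((n, 32)) < 0.2).astype(np.uint8)
    Xs[y == 1, :4] = 1  # structural signal
    Xm = rng.normal(size=(n, 12))
    Xm[y == 1, 0] += 2.0
    ids = [f"c{i:03d}" for i in range(n)]
    return Xs, Xm, y, ids


@pytest.fixture(scope="module")
def oof():
    Xs, Xm, y, ids = _toy_nested_inputs()
    cfg = RunConfig(seed=5, min_minority=10)
    return run_nested_cv(pd.DataFrame(Xs), pd.DataFrame(Xm), y, ids, cfg,
                         space=compact_space()), ids


class TestNestedCV:

    def test_covers_each_compound_exactly_once(self, oof):
        table, ids = oof
        assert sorted(table["compound_id"]) == sorted(ids)
        assert table["fold"].value_counts().tolist() == [20] * 5

    def test_feature_ranges(self, oof):
        table, _ = oof
        for col in ("p_struct_scaled", "p_morph_scaled", "s_struct"):
            assert table[col].between(0, 1).all()
        assert table["s_morph"].between(-1, 1).all()

    def test_leakage_sentinel(self):
        """Corrupting one fold's labels must not move that fold's features."""
        Xs, Xm, y, ids = _toy_nested_inputs()
        cfg = RunConfig(seed=5, min_minority=10)
        folds = np.arange(len(y)) % 5
        base = run_nested_cv(pd.DataFrame(Xs), pd.DataFrame(Xm), y, ids, cfg,
                             space=compact_space(), folds=folds)
        y_bad = y.copy()
        y_bad[folds == 2] = 1 - y_bad[folds == 2]
        corrupted = run_nested_cv(pd.DataFrame(Xs), pd.DataFrame(Xm), y_bad, ids,
                                  cfg, space=compact_space(), folds=folds)
        cols = ["p_struct_scaled", "p_morph_scaled", "s_struct", "s_morph"]
        a = base[base["fold"] == 2].sort_values("compound_id")[cols]
        b = corrupted[corrupted["fold"] == 2].sort_values("compound_id")[cols]
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())


@pytest.fixture(scope="module")
def model_and_data():
    Xs, _, y, _ = _toy_nested_inputs(n=120, seed=9)
    cfg = RunConfig(seed=9, min_minority=10)
    model = fit_final_model(pd.DataFrame(Xs[:80]), y[:80], "struct", cfg,
                            compact_space())
    return model, Xs, y


class TestFinalModel:

    def test_calibration_identity(self, model_and_data):
        model, _, _ = model_and_data
        t = model.calibration.threshold
        assert rescale_probability(t, t) == 0.5
        assert 0 < t < 1

    def test_probabilities_in_range(self, model_and_data):
        model, Xs, _ = model_and_data
        p = model.predict_scaled(pd.DataFrame(Xs[80:]))
        assert ((p >= 0) & (p <= 1)).all()

    def test_separable_assay_heldout_auc(self, model_and_data):
        from sklearn.metrics import roc_auc_score

        model, Xs, y = model_and_data
        p = model.predict_scaled(pd.DataFrame(Xs[80:]))
        assert roc_auc_score(y[80:], p) > 0.9
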