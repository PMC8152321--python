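"""Concatenation, sigmoid head, BCE, oversampling, and head training."""

import numpy as np
import pytest

import superfelt as sf
from superfelt import classifier_head as ch
from superfelt.errors import TrainingError


class TestConcatenate:
    def test_width_is_sum_of_parts(self, rng):
        out = ch.concatenate(rng.normal(size=(5, 64)), rng.normal(size=(5, 16)),
                             rng.normal(size=(5, 32)))
        assert out.shape == (5, 112)

    def test_single_layer_identity(self, rng):
        e = rng.normal(size=(4, 7))
        np.testing.assert_array_equal(ch.concatenate(e), e)

    def test_column_mapping_preserves_sources(self, rng):
        a, b = rng.normal(size=(3, 2)), rng.normal(size=(3, 3))
        out = ch.concatenate(a, b)
        np.testing.assert_array_equal(out[:, :2], a)
        np.testing.assert_array_equal(out[:, 2:], b)

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ch.concatenate(rng.normal(size=(3, 2)), rng.normal(size=(4, 2)))


class TestPredictProba:
    def test_zero_weights_no_bias_gives_half(self, rng):
        clf = ch.LinearSigmoidClassifier(np.zeros(5), None)
        np.testing.assert_array_equal(ch.predict_proba(clf, rng.normal(size=(6, 5))), 0.5)

    def test_matches_direct_formula(self, rng):
        w = rng.normal(size=8)
        x = rng.normal(size=(10, 8))
        clf = ch.LinearSigmoidClassifier(w, 0.3)
        expected = 1.0 / (1.0 + np.exp(-(x @ w + 0.3)))
        np.testing.assert_allclose(ch.predict_proba(clf, x), expected, rtol=1e-12)

    def test_outputs_strictly_inside_unit_interval(self, rng):
        clf = ch.LinearSigmoidClassifier(rng.normal(size=3) * 50, None)
        p = ch.predict_proba(clf, rng.normal(size=(100, 3)))
        assert np.all(p > 0.0) and np.all(p < 1.0)

    def test_width_mismatch_rejected(self, rng):
        clf = ch.LinearSigmoidClassifier(np.zeros(4), None)
        with pytest.raises(ValueError):
            ch.predict_proba(clf, rng.normal(size=(2, 5)))


class TestBCELoss:
    def test_perfect_prediction_near_zero(self):
        y = np.array([0.0, 1.0, 1.0])
        assert ch.bce_loss(y, y) <= 2e-7

    def test_uninformative_half_is_ln2(self):
        assert ch.bce_loss(np.full(9, 0.5), np.array([0, 1] * 4 + [0])) == pytest.approx(
            np.log(2), rel=1e-12
        )

    def test_matches_elementwise_formula(self, rng):
        p = rng.uniform(0.01, 0.99, 20)
        y = rng.integers(0, 2, 20).astype(float)
        expected = np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p)))
        assert ch.bce_loss(p, y) == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ch.bce_loss(np.zeros(3), np.zeros(4))


class TestOversample:
    def test_balances_to_majority_count(self):
        labels = np.array([0] * 6 + [1] * 2)
        idx = ch.oversample(labels, seed=0)
        assert len(idx) == 12
        assert int((labels[idx] == 0).sum()) == 6
        assert int((labels[idx] == 1).sum()) == 6

    def test_already_balanced_identity(self):
        labels = np.array([0, 1, 0, 1])
        np.testing.assert_array_equal(ch.oversample(labels, seed=3), np.arange(4))

    def test_contains_every_original_index(self, rng):
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        idx = ch.oversample(labels, seed=1)
        assert set(idx) >= set(range(30))

    def test_majority_never_duplicated(self):
        labels = np.array([0] * 10 + [1] * 3)
        idx = ch.oversample(labels, seed=5)
        counts = np.bincount(idx, minlength=13)
        assert np.all(counts[:10] == 1)

    def test_same_seed_identical(self):
        labels = np.array([0] * 7 + [1] * 2)
        np.testing.assert_array_equal(ch.oversample(labels, seed=9), ch.oversample(labels, seed=9))

    def test_single_class_rejected(self):
        with pytest.raises(TrainingError):
            ch.oversample(np.zeros(5, dtype=int), seed=0)


def _separable(seed=0, n=80):
    rng = np.random.default_rng(seed)
    y = (np.arange(n) % 4 == 0).astype(int)
    x = rng.normal(size=(n, 6))
    x[:, 0] += 6.0 * y
    return x[: n - 20], y[: n - 20], x[n - 20:], y[n - 20:]


class TestTrainClassifier:
    def test_zero_epochs_returns_seeded_init(self):
        x, y, xv, yv = _separable()
        cfg = ch.ClassifierConfig(max_epochs=0, patience=0, seed=8)
        clf = ch.train_classifier(x, y, xv, yv, cfg)
        rng = np.random.default_rng(8)
        expected = rng.uniform(-1 / np.sqrt(6), 1 / np.sqrt(6), size=6)
        np.testing.assert_array_equal(clf.weights, expected)
        assert clf.bias == 0.0

    def test_same_seed_identical_weights(self):
        x, y, xv, yv = _separable()
        cfg = ch.ClassifierConfig(max_epochs=20, patience=10, seed=2)
        a = ch.train_classifier(x, y, xv, yv, cfg)
        b = ch.train_classifier(x, y, xv, yv, cfg)
        assert a.weights.tobytes() == b.weights.tobytes()
        assert a.bias == b.bias

    def test_separable_embeddings_reach_perfect_validation_auc(self):
        x, y, xv, yv = _separable(seed=3)
        cfg = ch.ClassifierConfig(max_epochs=200, patience=200, seed=0)
        clf = ch.train_classifier(x, y, xv, yv, cfg)
        assert sf.roc_auc(ch.predict_proba(clf, xv), yv) == 1.0

    def test_single_class_validation_rejected(self):
        x, y, xv, yv = _separable()
        cfg = ch.ClassifierConfig(max_epochs=5, patience=2)
        with pytest.raises(TrainingError):
            ch.train_classifier(x, y, xv, np.zeros_like(yv), cfg)

    def test_bias_free_form_available(self):
        x, y, xv, yv = _separable()
        cfg = ch.ClassifierConfig(max_epochs=5, patience=2, include_bias=False, seed=0)
        clf = ch.train_classifier(x, y, xv, yv, cfg)
        assert clf.bias is None


class TestAUCInvariance:
    def test_auc_invariant_under_monotone_score_transform(self, rng):
        """AUC depends only on the score ordering, so any strictly
        increasing transform of the linear score leaves it unchanged."""
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        base = sf.roc_auc(scores, labels)
        for f in (np.exp, np.tanh, lambda s: 3 * s - 7, lambda s: s**3):
            assert sf.roc_auc(f(scores), labels) == pytest.approx(base, abs=1e-12)
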