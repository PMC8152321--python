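"""Encoder forward pass, batch-all triplet enumeration, loss, and training."""

import numpy as np
import pytest

import superfelt as sf
from superfelt import triplet_encoder as te
from superfelt.errors import ConfigurationError, TrainingError


def brute_force_triplet_loss(z, labels, margin):
    """Three-nested-loop oracle for the mean batch-all hinge loss."""
    n = len(labels)
    total, count = 0.0, 0
    for a in range(n):
        for p in range(n):
            for neg in range(n):
                if a != p and labels[a] == labels[p] and labels[a] != labels[neg]:
                    d_ap = np.linalg.norm(z[a] - z[p])
                    d_an = np.linalg.norm(z[a] - z[neg])
                    total += max(d_ap - d_an + margin, 0.0)
                    count += 1
    return total / count if count else 0.0


def _model(w):
    w = np.asarray(w, dtype=float)
    return te.EncoderModel("expression", w, [f"g{j}" for j in range(w.shape[0])],
                           te.EncoderConfig(output_dim=w.shape[1]))


class TestEncode:
    def test_zero_weights_give_zero_embedding(self, rng):
        m = _model(np.zeros((4, 3)))
        assert np.all(te.encode(m, rng.normal(size=(5, 4))) == 0.0)

    def test_negative_projections_clamped(self):
        m = _model(-np.eye(3))
        out = te.encode(m, np.ones((2, 3)))
        assert np.all(out == 0.0)

    def test_matches_direct_product_with_relu(self, rng):
        w = rng.normal(size=(6, 4))
        x = rng.normal(size=(8, 6))
        np.testing.assert_allclose(
            te.encode(_model(w), x), np.maximum(x @ w, 0.0), rtol=1e-12
        )

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            te.encode(_model(np.zeros((4, 2))), rng.normal(size=(3, 5)))


class TestMakeTriplets:
    def test_two_vs_two(self):
        tb = te.make_triplets(np.array([1, 1, 0, 0]))
        assert len(tb) == 8  # 4 anchors x 1 positive x 2 negatives

    def test_three_vs_two(self):
        tb = te.make_triplets(np.array([1, 1, 1, 0, 0]))
        assert len(tb) == 3 * 2 * 2 + 2 * 1 * 3

    def test_single_class_yields_empty_with_warning(self):
        with pytest.warns(UserWarning):
            tb = te.make_triplets(np.array([1, 1, 1]))
        assert len(tb) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_triplet_validity_invariants(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, 12)
        if np.unique(labels).size < 2:
            labels[0] = 1 - labels[0]
        tb = te.make_triplets(labels)
        assert np.all(labels[tb.anchor] == labels[tb.positive])
        assert np.all(labels[tb.anchor] != labels[tb.negative])
        assert np.all(tb.anchor != tb.positive)
        # count identity: nS(nS-1)nR + nR(nR-1)nS
        ns, nr = int(labels.sum()), int((1 - labels).sum())
        assert len(tb) == ns * (ns - 1) * nr + nr * (nr - 1) * ns


class TestTripletLoss:
    def test_satisfied_margin_gives_zero(self):
        # anchor == positive, negative 2 away, margin 1: max(0 - 2 + 1, 0) = 0
        z = np.array([[0.0], [0.0], [2.0]])
        tb = te.TripletBatch(np.array([0]), np.array([1]), np.array([2]))
        assert te.triplet_loss(z, tb, margin=1.0) == 0.0

    def test_equidistant_pair_pays_the_margin(self):
        z = np.array([[0.0], [1.0], [-1.0]])
        tb = te.TripletBatch(np.array([0]), np.array([1]), np.array([2]))
        assert te.triplet_loss(z, tb, margin=0.5) == pytest.approx(0.5)

    def test_empty_batch_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            tb = te.make_triplets(np.array([0, 0]))
        with pytest.warns(UserWarning):
            assert te.triplet_loss(np.zeros((2, 2)), tb, 1.0) == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(6, 21))
        z = rng.normal(size=(n, 5))
        labels = rng.integers(0, 2, n)
        if np.unique(labels).size < 2:
            labels[0] = 1 - labels[0]
        got = te.triplet_loss(z, te.make_triplets(labels), 1.0)
        assert got == pytest.approx(brute_force_triplet_loss(z, labels, 1.0), abs=1e-9)

    def test_fast_split_loss_equals_triplet_path(self, rng):
        z = rng.normal(size=(25, 4))
        labels = rng.integers(0, 2, 25)
        a = te.triplet_loss(z, te.make_triplets(labels), 0.7)
        assert te.batch_all_loss(z, labels, 0.7) == pytest.approx(a, abs=1e-10)

    def test_permutation_invariance(self, rng):
        z = rng.normal(size=(15, 3))
        labels = rng.integers(0, 2, 15)
        labels[:2] = [0, 1]
        perm = rng.permutation(15)
        a = te.triplet_loss(z, te.make_triplets(labels), 1.0)
        b = te.triplet_loss(z[perm], te.make_triplets(labels[perm]), 1.0)
        assert a == pytest.approx(b, abs=1e-9)

    def test_margin_satisfied_identity(self, rng):
        """Loss is exactly 0 when every inter-class gap exceeds the margin."""
        z = np.vstack([rng.normal(size=(5, 3)), rng.normal(size=(5, 3)) + 100.0])
        labels = np.array([0] * 5 + [1] * 5)
        assert te.triplet_loss(z, te.make_triplets(labels), 1.0) == 0.0


def _training_data(seed=0, n=120):
    cfg = sf.SimulationConfig(n_samples=n, n_features=(40, 20, 20),
                              n_informative=(15, 5, 5), seed=seed)
    ds = sf.simulate_dataset(cfg)
    x = ds.expression.values[:, :15]
    y = ds.labels.labels
    return x[: n - 40], y[: n - 40], x[n - 40:], y[n - 40:]


def _separation_ratio(z, y):
    inter = np.mean([np.linalg.norm(a - b) for a in z[y == 1] for b in z[y == 0]])
    intra = np.mean(
        [np.linalg.norm(a - b) for c in (0, 1)
         for i, a in enumerate(z[y == c]) for b in z[y == c][i + 1:]]
    )
    return inter / intra


class TestTrainEncoder:
    def test_zero_epochs_returns_seeded_init(self):
        x, y, xv, yv = _training_data()
        cfg = te.EncoderConfig(output_dim=8, max_epochs=0, patience=0, seed=4)
        m1 = te.train_encoder(x, y, xv, yv, cfg)
        rng = np.random.default_rng(4)
        expected = rng.uniform(-1 / np.sqrt(15), 1 / np.sqrt(15), size=(15, 8))
        np.testing.assert_array_equal(m1.weights, expected)

    def test_same_seed_bitwise_identical(self):
        x, y, xv, yv = _training_data()
        cfg = te.EncoderConfig(output_dim=8, max_epochs=10, patience=5, seed=7)
        m1 = te.train_encoder(x, y, xv, yv, cfg)
        m2 = te.train_encoder(x, y, xv, yv, cfg)
        assert m1.weights.tobytes() == m2.weights.tobytes()

    def test_single_class_training_rejected(self):
        x, y, xv, yv = _training_data()
        cfg = te.EncoderConfig(output_dim=4, max_epochs=5, patience=2)
        with pytest.raises(TrainingError):
            te.train_encoder(x, np.zeros_like(y), xv, yv, cfg)

    def test_training_improves_class_separation(self):
        x, y, xv, yv = _training_data(seed=13)
        cfg = te.EncoderConfig(output_dim=16, max_epochs=40, patience=10, seed=1)
        init = te.train_encoder(x, y, xv, yv,
                                te.EncoderConfig(output_dim=16, max_epochs=0,
                                                 patience=0, seed=1))
        trained = te.train_encoder(x, y, xv, yv, cfg)
        r0 = _separation_ratio(te.encode(init, xv), yv)
        r1 = _separation_ratio(te.encode(trained, xv), yv)
        assert r1 > r0

    def test_embeddings_nonnegative_after_training(self):
        x, y, xv, yv = _training_data(seed=2)
        cfg = te.EncoderConfig(output_dim=6, max_epochs=10, patience=5, seed=2)
        model = te.train_encoder(x, y, xv, yv, cfg)
        assert np.all(te.encode(model, xv) >= 0.0)

    def test_history_records_both_losses(self):
        x, y, xv, yv = _training_data()
        cfg = te.EncoderConfig(output_dim=4, max_epochs=5, patience=5, seed=0)
        model = te.train_encoder(x, y, xv, yv, cfg)
        assert model.history and {"train_loss", "val_loss"} <= set(model.history[0])

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            te.EncoderConfig(output_dim=0)
        with pytest.raises(ConfigurationError):
            te.EncoderConfig(output_dim=4, dropout_rate=1.0)
        with pytest.raises(ConfigurationError):
            te.EncoderConfig(output_dim=4, max_epochs=5, patience=9)
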