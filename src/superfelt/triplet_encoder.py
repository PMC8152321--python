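"""Supervised encoders trained with triplet loss (one per omics layer).

Each encoder is a single fully connected layer with ReLU activation,

    E(X') = relu(X' W),    W : M' x M_out,

trained to pull same-class samples together and push opposite-class
samples apart. Within every mini-batch all valid (anchor, positive,
negative) index triples are enumerated (batch-all mining): an anchor and a
positive share a label and differ as samples, the negative has the other
label. The per-triplet hinge

    L(a, p, n) = max(d(E(a), E(p)) - d(E(a), E(n)) + margin, 0)

with Euclidean d is averaged over all triplets, making the value invariant
to batch composition. Overfitting is controlled by dropout on the ReLU
output, L2 weight decay, and early stopping on the validation triplet
loss. The sensitive minority is oversampled once per training run so that
batches contain both classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._optim import Adam
from .classifier_head import oversample
from .errors import ConfigurationError, TrainingError

_EPS = 1e-12


@dataclass
class EncoderConfig:
    output_dim: int
    margin: float = 1.0
    learning_rate: float = 0.01
    weight_decay: float = 1e-4
    dropout_rate: float = 0.1
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    squared_distance: bool = False

    def __post_init__(self) -> None:
        if self.output_dim < 1:
            raise ConfigurationError("output_dim must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.margin < 0:
            raise ConfigurationError("margin must be >= 0")
        if self.patience > self.max_epochs and self.max_epochs > 0:
            raise ConfigurationError("patience must not exceed max_epochs")


@dataclass
class EncoderModel:
    """Trained weights of one omics encoder."""

    kind: str
    weights: np.ndarray  # (n_input_features, output_dim)
    feature_ids: list[str]
    config: EncoderConfig
    history: list[dict] = field(default_factory=list)


@dataclass
class TripletBatch:
    """Anchor/positive/negative index triples into one batch."""

    anchor: np.ndarray
    positive: np.ndarray
    negative: np.ndarray

    def __len__(self) -> int:
        return len(self.anchor)


def encode(model: EncoderModel, x: np.ndarray) -> np.ndarray:
    """ReLU-clamped linear embedding; dropout is never applied here."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.weights.shape[0]:
        raise ValueError(
            f"input width {x.shape[-1] if x.ndim == 2 else x.shape} does not "
            f"match encoder input dimension {model.weights.shape[0]}"
        )
    return np.maximum(x @ model.weights, 0.0)


def make_triplets(labels: np.ndarray) -> TripletBatch:
    """Enumerate every valid triplet in a batch (batch-all mining).

    Anchors come from both classes: with a sensitive anchor, sensitive
    samples are positives and resistant samples negatives, and vice versa.
    A single-class batch yields an empty TripletBatch with a warning.
    """
    labels = np.asarray(labels, dtype=int)
    anchors, positives, negatives = [], [], []
    for cls in (1, 0):
        same = np.where(labels == cls)[0]
        other = np.where(labels != cls)[0]
        if same.size < 2 or other.size == 0:
            continue
        # ordered (a, p) pairs with a != p, each against every negative
        a = np.repeat(same, same.size - 1)
        p = np.concatenate([same[same != s] for s in same])
        anchors.append(np.repeat(a, other.size))
        positives.append(np.repeat(p, other.size))
        negatives.append(np.tile(other, a.size))
    if not anchors:
        warnings.warn("batch has no valid triplets (single class)", stacklevel=2)
        empty = np.empty(0, dtype=int)
        return TripletBatch(empty, empty.copy(), empty.copy())
    return TripletBatch(
        np.concatenate(anchors), np.concatenate(positives), np.concatenate(negatives)
    )


def _distances(diff: np.ndarray, squared: bool) -> np.ndarray:
    sq = np.einsum("ij,ij->i", diff, diff)
    return sq if squared else np.sqrt(sq)


def triplet_loss(
    embeddings: np.ndarray,
    triplets: TripletBatch,
    margin: float,
    squared: bool = False,
) -> float:
    """Mean batch-all triplet hinge loss (0 for an empty batch)."""
    if len(triplets) == 0:
        warnings.warn("empty triplet batch; loss defined as 0", stacklevel=2)
        return 0.0
    z = np.asarray(embeddings, dtype=float)
    d_ap = _distances(z[triplets.anchor] - z[triplets.positive], squared)
    d_an = _distances(z[triplets.anchor] - z[triplets.negative], squared)
    return float(np.mean(np.maximum(d_ap - d_an + margin, 0.0)))


def batch_all_loss(
    z: np.ndarray, labels: np.ndarray, margin: float, squared: bool = False
) -> float:
    """Mean hinge over all valid triplets, via pairwise distances.

    Identical to ``triplet_loss(z, make_triplets(labels), ...)`` but never
    materializes the triplet index arrays, so it scales to whole splits;
    used for the per-epoch train/validation losses. Returns 0 for a
    single-class split.
    """
    z = np.asarray(z, dtype=float)
    labels = np.asarray(labels, dtype=int)
    sq = np.einsum("ij,ij->i", z, z)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (z @ z.T), 0.0)
    dist = d2 if squared else np.sqrt(d2)
    total, count = 0.0, 0
    for cls in (1, 0):
        s = np.where(labels == cls)[0]
        o = np.where(labels != cls)[0]
        if s.size < 2 or o.size == 0:
            continue
        d_ap = dist[np.ix_(s, s)]
        d_an = dist[np.ix_(s, o)]
        h = np.maximum(d_ap[:, :, None] - d_an[:, None, :] + margin, 0.0)
        h[np.arange(s.size), np.arange(s.size), :] = 0.0  # drop a == p
        total += float(h.sum())
        count += s.size * (s.size - 1) * o.size
    return total / count if count else 0.0


def _triplet_loss_grad(
    z: np.ndarray, triplets: TripletBatch, margin: float, squared: bool
) -> tuple[float, np.ndarray]:
    """Loss and dLoss/dz for the mean batch-all hinge."""
    k = len(triplets)
    ap = z[triplets.anchor] - z[triplets.positive]
    an = z[triplets.anchor] - z[triplets.negative]
    d_ap = _distances(ap, squared)
    d_an = _distances(an, squared)
    h = d_ap - d_an + margin
    active = h > 0
    loss = float(np.maximum(h, 0.0).mean())
    dz = np.zeros_like(z)
    if active.any():
        if squared:
            u_ap = 2.0 * ap[active]
            u_an = 2.0 * an[active]
        else:
            u_ap = ap[active] / np.maximum(d_ap[active], _EPS)[:, None]
            u_an = an[active] / np.maximum(d_an[active], _EPS)[:, None]
        a, p, n = triplets.anchor[active], triplets.positive[active], triplets.negative[active]
        np.add.at(dz, a, (u_ap - u_an) / k)
        np.add.at(dz, p, -u_ap / k)
        np.add.at(dz, n, u_an / k)
    return loss, dz


def _init_weights(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(n_in)
    return rng.uniform(-bound, bound, size=(n_in, n_out))


def train_encoder(
    x: np.ndarray,
    labels: np.ndarray,
    x_val: np.ndarray,
    labels_val: np.ndarray,
    cfg: EncoderConfig,
    kind: str = "expression",
    feature_ids: list[str] | None = None,
) -> EncoderModel:
    """Train one omics encoder by mini-batch Adam on the triplet loss.

    Early stopping monitors the batch-all triplet loss over the full
    validation split; the weights of the best validation epoch are
    returned. Fully reproducible given ``cfg.seed``.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels, dtype=int)
    x_val = np.asarray(x_val, dtype=float)
    labels_val = np.asarray(labels_val, dtype=int)
    for y, name in ((labels, "training"), (labels_val, "validation")):
        if np.unique(y).size < 2:
            raise TrainingError(f"{name} labels contain a single class")

    rng = np.random.default_rng(cfg.seed)
    w = _init_weights(rng, x.shape[1], cfg.output_dim)
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(x.shape[1])]
    model = EncoderModel(kind, w, list(feature_ids), cfg)
    if cfg.max_epochs == 0:
        return model

    train_idx = oversample(labels, rng=rng)
    opt = Adam([w.shape], lr=cfg.learning_rate)
    keep = 1.0 - cfg.dropout_rate

    best_w = w.copy()
    best_val = np.inf
    stale = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(train_idx)
        for start in range(0, order.size, cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                triplets = make_triplets(labels[batch])
            if len(triplets) == 0:
                continue
            xb = x[batch]
            pre = xb @ w
            zr = np.maximum(pre, 0.0)
            if cfg.dropout_rate > 0:
                mask = (rng.random(zr.shape) < keep) / keep
                zd = zr * mask
            else:
                mask = None
                zd = zr
            _, dz = _triplet_loss_grad(zd, triplets, cfg.margin, cfg.squared_distance)
            if mask is not None:
                dz = dz * mask
            dz *= pre > 0
            grad = xb.T @ dz + cfg.weight_decay * w
            opt.step([w], [grad])

        train_loss = batch_all_loss(
            np.maximum(x @ w, 0.0), labels, cfg.margin, cfg.squared_distance
        )
        val_loss = batch_all_loss(
            np.maximum(x_val @ w, 0.0), labels_val, cfg.margin, cfg.squared_distance
        )
        model.history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_w = w.copy()
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    model.weights = best_w
    return model
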