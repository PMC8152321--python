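"""Linear sigmoid classifier over concatenated frozen embeddings.

The encoded omics layers are concatenated in the fixed order
expression + mutation + cna, and a single-layer classifier

    p = sigmoid(X_hat w + b)

is trained with binary cross-entropy on a minority-oversampled training
set. The encoders are trained beforehand and frozen: nothing here touches
their weights. A shallow head suffices because the embedding stage already
organizes the data by response; depth would only invite overfitting on
panels with few sensitive samples. Regularized with input dropout, L2
weight decay, and early stopping on validation AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._optim import Adam
from .errors import ConfigurationError, TrainingError
from .metrics import roc_auc

_CLIP = 1e-7


@dataclass
class ClassifierConfig:
    learning_rate: float = 0.01
    weight_decay: float = 1e-4
    dropout_rate: float = 0.1
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    include_bias: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.patience > self.max_epochs and self.max_epochs > 0:
            raise ConfigurationError("patience must not exceed max_epochs")


@dataclass
class LinearSigmoidClassifier:
    weights: np.ndarray  # (input_dim,)
    bias: float | None = None  # None when the pure bias-free form is used

    @property
    def input_dim(self) -> int:
        return self.weights.size


def concatenate(*embeddings: np.ndarray) -> np.ndarray:
    """Column-concatenate embeddings (expression, mutation, cna order)."""
    mats = [np.asarray(e, dtype=float) for e in embeddings if e is not None and e.size]
    if not mats:
        raise ValueError("nothing to concatenate")
    rows = {m.shape[0] for m in mats}
    if len(rows) != 1:
        raise ValueError(f"row-count mismatch across layers: {sorted(rows)}")
    return mats[0] if len(mats) == 1 else np.hstack(mats)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def predict_proba(clf: LinearSigmoidClassifier, xhat: np.ndarray) -> np.ndarray:
    """Sigmoid of the linear score; values strictly in (0, 1)."""
    xhat = np.asarray(xhat, dtype=float)
    if xhat.ndim != 2 or xhat.shape[1] != clf.input_dim:
        raise ValueError(
            f"input width {xhat.shape} does not match classifier dimension {clf.input_dim}"
        )
    z = xhat @ clf.weights
    if clf.bias is not None:
        z = z + clf.bias
    # keep probabilities strictly inside (0,1) even when the score saturates
    return np.clip(_sigmoid(z), 1e-15, 1.0 - 1e-15)


def bce_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy with probabilities clipped to [1e-7, 1-1e-7]."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must have the same length")
    p = np.clip(probs, _CLIP, 1.0 - _CLIP)
    return float(-np.mean(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p)))


def oversample(
    labels: np.ndarray,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Balance classes by duplicating minority samples.

    Returns indices containing every original sample once plus minority
    samples re-drawn with replacement until class counts are equal. The
    majority class is never duplicated; an already balanced input is
    returned unchanged.
    """
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=2)
    if counts[0] == 0 or counts[1] == 0:
        raise TrainingError("oversampling needs both classes present")
    base = np.arange(labels.size)
    deficit = abs(int(counts[0]) - int(counts[1]))
    if deficit == 0:
        return base
    if rng is None:
        rng = np.random.default_rng(seed)
    minority = int(np.argmin(counts))
    extra = rng.choice(np.where(labels == minority)[0], size=deficit, replace=True)
    return np.concatenate([base, extra])


def train_classifier(
    xhat: np.ndarray,
    labels: np.ndarray,
    xhat_val: np.ndarray,
    labels_val: np.ndarray,
    cfg: ClassifierConfig,
) -> LinearSigmoidClassifier:
    """Fit the sigmoid head by mini-batch Adam on oversampled BCE.

    Validation AUC drives early stopping (model selection throughout the
    protocol is AUC-based); the best-validation-AUC weights are returned.
    Raises :class:`TrainingError` if either split is single-class.
    """
    xhat = np.asarray(xhat, dtype=float)
    labels = np.asarray(labels, dtype=int)
    xhat_val = np.asarray(xhat_val, dtype=float)
    labels_val = np.asarray(labels_val, dtype=int)
    for y, name in ((labels, "training"), (labels_val, "validation")):
        if np.unique(y).size < 2:
            raise TrainingError(f"{name} labels contain a single class")

    rng = np.random.default_rng(cfg.seed)
    n_in = xhat.shape[1]
    bound = 1.0 / np.sqrt(n_in)
    w = rng.uniform(-bound, bound, size=n_in)
    bvec = np.zeros(1) if cfg.include_bias else None

    def current() -> LinearSigmoidClassifier:
        return LinearSigmoidClassifier(
            w.copy(), float(bvec[0]) if bvec is not None else None
        )

    if cfg.max_epochs == 0:
        return current()

    train_idx = oversample(labels, rng=rng)
    params = [w] + ([bvec] if bvec is not None else [])
    opt = Adam([p.shape for p in params], lr=cfg.learning_rate)
    keep = 1.0 - cfg.dropout_rate

    best_auc, best_clf = -np.inf, current()
    stale = 0
    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(train_idx)
        for start in range(0, order.size, cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            xb = xhat[batch]
            if cfg.dropout_rate > 0:
                xb = xb * ((rng.random(xb.shape) < keep) / keep)
            z = xb @ w + (bvec[0] if bvec is not None else 0.0)
            p = _sigmoid(z)
            dz = (p - labels[batch]) / batch.size
            gw = xb.T @ dz + cfg.weight_decay * w
            grads = [gw] + ([np.array([dz.sum()])] if bvec is not None else [])
            opt.step(params, grads)
        val_auc = roc_auc(predict_proba(current(), xhat_val), labels_val)
        if val_auc > best_auc + 1e-12:
            best_auc = val_auc
            best_clf = current()
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    return best_clf
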