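"""Threshold-free classification metrics."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .errors import TrainingError


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC via the Mann-Whitney statistic, ties half-credited.

    Equals the probability that a uniformly drawn positive (sensitive,
    label 1) sample outscores a uniformly drawn negative one, counting a
    tie as 1/2. Exact and threshold-free.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise TrainingError("AUC undefined: only one class present")
    ranks = rankdata(scores)  # average ranks handle ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
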