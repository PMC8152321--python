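"""Variance-threshold feature selection with an elbow-chosen cutoff.

Low-variance features are assumed to carry little response-relevant
information, so each omics layer is reduced to its high-variance features
before encoding. The cutoff is found on the descending sorted variance
curve (a scree plot): after min-max scaling both axes to [0, 1], the bend
is located at the point farthest from the chord joining the first and
last points; when that point has already fallen below the chord the knee
is the point just before it, so the cutoff keeps the high-variance
plateau only. The knee's variance becomes the threshold and features with
variance >= threshold are kept. For a collinear (or all-equal) profile no
knee exists and the caller keeps all features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateCurveError, InsufficientDataError, MaskMismatchError
from .omics_data import OmicsMatrix

_TOL = 1e-12


@dataclass
class FeatureMask:
    """Selected features of one omics layer, with audit information."""

    kind: str
    feature_ids: list[str]
    threshold: float
    variances: np.ndarray  # training-set variance of every source feature

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "feature_ids": list(self.feature_ids),
            "threshold": float(self.threshold),
            "variances": [float(v) for v in self.variances],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureMask":
        return cls(d["kind"], list(d["feature_ids"]), d["threshold"], np.array(d["variances"]))


def feature_variances(m: OmicsMatrix) -> np.ndarray:
    """Per-feature sample variance (denominator N-1), in feature order."""
    if m.n_samples < 2:
        raise InsufficientDataError("variance needs at least 2 samples")
    return m.values.var(axis=0, ddof=1)


def elbow_threshold(variances: np.ndarray) -> float:
    """Knee of the descending sorted variance curve; ties break toward the
    smaller index (fewer features kept).

    The farthest point from the chord locates the bend. When that point
    lies *above* the chord (plateau-then-cliff profile) it is the knee
    itself; when it lies *below* (the drop has already happened by that
    index) the knee is the point just before it, so the threshold keeps
    the plateau only. Raises :class:`DegenerateCurveError` when fewer than
    3 values exist, all values are equal, or the curve is collinear.
    """
    v = np.sort(np.asarray(variances, dtype=float))[::-1]
    if v.size < 3:
        raise DegenerateCurveError("need at least 3 variance values")
    if np.unique(v).size < 2:
        raise DegenerateCurveError("all variances equal; no knee")
    n = v.size
    x = np.arange(n) / (n - 1)
    y = (v - v[-1]) / (v[0] - v[-1])
    # chord runs from (0,1) to (1,0); signed distance above it is prop. to x+y-1
    signed = x + y - 1.0
    if np.abs(signed).max() <= _TOL:
        raise DegenerateCurveError("variance curve is collinear; no knee")
    i = int(np.argmax(np.abs(signed)))
    if signed[i] < 0:
        i -= 1
    return float(v[i])


def fit_mask(m: OmicsMatrix, top_k: int | None = None) -> FeatureMask:
    """Fit a variance mask on (training) samples only.

    ``top_k`` overrides the elbow rule with a fixed feature count, mirroring
    protocols that fix the selected-feature budget per omics layer. On a
    degenerate (knee-less) profile all features are kept and the minimum
    variance is recorded as the threshold.
    """
    variances = feature_variances(m)
    if top_k is not None:
        k = min(top_k, m.n_features)
        threshold = float(np.sort(variances)[::-1][k - 1])
    else:
        try:
            threshold = elbow_threshold(variances)
        except DegenerateCurveError:
            threshold = float(variances.min())
    keep = variances >= threshold
    selected = [f for f, k_ in zip(m.feature_ids, keep) if k_]
    return FeatureMask(m.kind, selected, threshold, variances)


def apply_mask(m: OmicsMatrix, mask: FeatureMask) -> OmicsMatrix:
    """Column-subset ``m`` to the mask's features (mask order)."""
    missing = set(mask.feature_ids) - set(m.feature_ids)
    if missing:
        raise MaskMismatchError(
            f"matrix lacks {len(missing)} mask features, e.g. {sorted(missing)[:3]}"
        )
    pos = {f: j for j, f in enumerate(m.feature_ids)}
    cols = [pos[f] for f in mask.feature_ids]
    return OmicsMatrix(list(m.sample_ids), list(mask.feature_ids), m.values[:, cols], m.kind)
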