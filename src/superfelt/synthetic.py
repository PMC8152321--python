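"""Label-structured multi-omics simulator and bimodal ln(IC50) generator.

The simulator emulates the regime of per-drug cell-line panels: a heavy
excess of resistant over sensitive samples (default 85/15), a small set of
informative features carrying a class-dependent signal, and a large body of
low-variance noise features so variance-based feature selection has a
detectable knee. Informative features sit at known, returned positions so
recovery is directly assertable. It makes no attempt to model batch effects
or gene-gene correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .omics_data import IC50Table, LabelVector, MultiOmicsDataset, OmicsMatrix

_PREFIX = {"expression": "EXPR", "mutation": "MUT", "cna": "CNA"}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated drug panel.

    ``effect_size`` is the between-class mean shift of informative
    expression/CNA features, in units of their within-class noise sd (1.0).
    ``noise_feature_variance_floor`` bounds the variance of non-informative
    features from below; their sds are drawn uniformly between sqrt(floor)
    and 0.5, keeping every noise variance well under the informative
    variance of ~1 + p(1-p)*effect_size^2.
    """

    n_samples: int = 400
    sensitive_fraction: float = 0.15
    n_features: tuple[int, int, int] = (1000, 500, 500)  # expression, mutation, cna
    n_informative: tuple[int, int, int] = (30, 20, 20)
    effect_size: float = 1.5
    mut_rate_background: float = 0.02
    mut_rate_informative_sensitive: float = 0.4
    noise_feature_variance_floor: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.sensitive_fraction < 1.0:
            raise ConfigurationError("sensitive_fraction must be in (0, 1)")
        for k, m in zip(self.n_informative, self.n_features):
            if k > m:
                raise ConfigurationError("n_informative may not exceed n_features")
        for r in (self.mut_rate_background, self.mut_rate_informative_sensitive):
            if not 0.0 < r < 1.0:
                raise ConfigurationError("mutation rates must be in (0, 1)")
        if self.noise_feature_variance_floor <= 0:
            raise ConfigurationError("noise_feature_variance_floor must be positive")
        n_sens = round(self.n_samples * self.sensitive_fraction)
        if n_sens < 1 or n_sens > self.n_samples - 1:
            raise ConfigurationError(
                f"n={self.n_samples} with sensitive_fraction="
                f"{self.sensitive_fraction} leaves a class empty"
            )


def _feature_ids(kind: str, n: int) -> list[str]:
    width = len(str(max(n - 1, 0)))
    return [f"{_PREFIX[kind]}{i:0{width}d}" for i in range(n)]


def _continuous_layer(
    rng: np.random.Generator,
    kind: str,
    labels: np.ndarray,
    n_features: int,
    n_informative: int,
    effect_size: float,
    var_floor: float,
) -> OmicsMatrix:
    n = labels.size
    values = np.empty((n, n_features))
    # informative block first: unit noise plus a class-dependent mean shift
    values[:, :n_informative] = rng.normal(size=(n, n_informative))
    values[:, :n_informative] += effect_size * labels[:, None]
    n_noise = n_features - n_informative
    if n_noise:
        sds = rng.uniform(np.sqrt(var_floor), 0.5, size=n_noise)
        values[:, n_informative:] = rng.normal(scale=sds, size=(n, n_noise))
    return OmicsMatrix(
        [f"S{i:04d}" for i in range(n)], _feature_ids(kind, n_features), values, kind
    )


def simulate_dataset(cfg: SimulationConfig) -> MultiOmicsDataset:
    """Draw one multi-omics panel, fully determined by ``cfg.seed``.

    Informative features occupy the first ``n_informative`` columns of each
    layer; their IDs (and the low-variance noise set) are listed in the
    returned dataset's ``metadata`` for recovery tests.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    n_sens = round(n * cfg.sensitive_fraction)
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[:n_sens]] = 1

    ne, nm, nc = cfg.n_features
    ke, km, kc = cfg.n_informative
    expression = _continuous_layer(
        rng, "expression", labels, ne, ke, cfg.effect_size, cfg.noise_feature_variance_floor
    )
    cna = _continuous_layer(
        rng, "cna", labels, nc, kc, cfg.effect_size, cfg.noise_feature_variance_floor
    )

    rates = np.full((n, nm), cfg.mut_rate_background)
    rates[labels == 1, :km] = cfg.mut_rate_informative_sensitive
    mut_values = (rng.random((n, nm)) < rates).astype(float)
    sample_ids = expression.sample_ids
    mutation = OmicsMatrix(list(sample_ids), _feature_ids("mutation", nm), mut_values, "mutation")

    meta = {
        "informative_features": {
            "expression": expression.feature_ids[:ke],
            "mutation": mutation.feature_ids[:km],
            "cna": cna.feature_ids[:kc],
        },
        "noise_features": {
            "expression": expression.feature_ids[ke:],
            "mutation": mutation.feature_ids[km:],
            "cna": cna.feature_ids[kc:],
        },
        "config": cfg,
    }
    return MultiOmicsDataset(
        expression, mutation, cna, LabelVector(list(sample_ids), labels), "simulated", meta
    )


def simulate_ic50(
    n: int,
    modes: tuple[tuple[float, float, float], ...] = ((-3.0, 0.5, 0.2), (1.0, 0.5, 0.8)),
    seed: int = 0,
) -> IC50Table:
    """Draw ln(IC50) values from a two-component normal mixture.

    ``modes`` is a pair of (mean, sd, weight) triples — by default a 20%
    sensitive component at ln(IC50) = -3 and an 80% resistant component at
    +1, both sd 0.5. True component membership (index into ``modes``) is
    stored in the table's ``metadata["component"]``.
    """
    means, sds, weights = (np.array(col, dtype=float) for col in zip(*modes))
    if np.any(sds <= 0):
        raise ConfigurationError("mixture sds must be positive")
    if not np.isclose(weights.sum(), 1.0):
        raise ConfigurationError("mixture weights must sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(modes), size=n, p=weights)
    vals = rng.normal(means[comp], sds[comp])
    width = len(str(max(n - 1, 0)))
    table = IC50Table([f"C{i:0{width}d}" for i in range(n)], vals)
    table.metadata["component"] = comp
    table.metadata["modes"] = [tuple(m) for m in modes]
    return table
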