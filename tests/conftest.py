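import numpy as np
import pytest

import superfelt as sf


@pytest.fixture(scope="session")
def small_panel() -> sf.MultiOmicsDataset:
    """A 200-sample simulated panel shared (read-only) across tests."""
    cfg = sf.SimulationConfig(
        n_samples=200, n_features=(200, 100, 100), n_informative=(30, 20, 20), seed=11
    )
    return sf.simulate_dataset(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def fast_hp() -> sf.HyperParams:
    """Small, quick hyperparameter set used throughout the suite."""
    return sf.HyperParams(
        output_dims={"expression": 32, "cna": 16, "mutation": 8},
        encoder_epochs=30,
        encoder_patience=8,
        classifier_epochs=60,
        classifier_patience=12,
    )
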