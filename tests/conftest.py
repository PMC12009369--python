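import numpy as np
import pytest

from ttdml import (ModelConfig, NormalizationStats, PreprocessConfig,
                   SimulationConfig, prepare_cohort, simulate_cohort,
                   temporal_split)
from ttdml.model import make_model


@pytest.fixture(scope="session")
def small_cohort():
    cohort, truth = simulate_cohort(SimulationConfig(n_patients=120, seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def small_split(small_cohort):
    cohort, _ = small_cohort
    train_c, test_c = temporal_split(cohort)
    stats = NormalizationStats.fit(train_c)
    pre = PreprocessConfig()
    return {
        "train_cohort": train_c,
        "test_cohort": test_c,
        "stats": stats,
        "train": prepare_cohort(train_c, stats, pre),
        "test": prepare_cohort(test_c, stats, pre),
    }


@pytest.fixture(scope="session")
def tiny_model(small_split):
    """A briefly-trained ODE-RNN for API-level tests (not accuracy tests)."""
    model = make_model("ode_rnn", ModelConfig(seed=0, epochs=3, hidden_dim=16,
                                              phenotype_dim=8))
    model.fit(small_split["train"])
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
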