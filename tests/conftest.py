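import numpy as np
import pytest

from seedflank.actpred import PredictorConfig, train_predictor
from seedflank.seqcore import SeedSpec
from seedflank.synthdata import default_config, simulate_dataset


@pytest.fixture(scope="session")
def toy_spec():
    return SeedSpec(32, (("TATAAT", 13),), "toy")


@pytest.fixture(scope="session")
def small_corpus():
    """300 synthetic 50-bp promoters with the sigma-70 seed geometry."""
    return simulate_dataset(default_config(n=300, window_length=50,
                                           noise_sd=0.05, rng_seed=11))


@pytest.fixture(scope="session")
def small_sim_config():
    return default_config(n=300, window_length=50, noise_sd=0.05, rng_seed=11)


def small_predictor_config(**overrides):
    base = dict(window_length=50, conv1_channels=16, conv1_kernel=5,
                lstm_hidden=8, dense_blocks=(1, 1, 2, 1), growth_rate=8,
                batch_size=32, learning_rate=2e-3, max_epochs=6, patience=6,
                rng_seed=0)
    base.update(overrides)
    return PredictorConfig(**base)


@pytest.fixture(scope="session")
def small_predictor(small_corpus):
    """A quickly trained predictor shared by introspection tests."""
    model, report = train_predictor(small_corpus, small_predictor_config())
    return model, report


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))
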