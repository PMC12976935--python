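import numpy as np
import pytest

from funclust import benchmark
from funclust.io import RunConfig


@pytest.fixture(scope="session")
def small_benchmark():
    """A reduced benchmark instance for fast unit tests (250 samples)."""
    spec = benchmark.BenchmarkSpec(n_samples=250, seed=7)
    X, F, truth = benchmark.generate_benchmark(spec)
    return X, F, truth


@pytest.fixture()
def fast_config():
    """Small network / short training for smoke-level training tests."""
    return RunConfig(
        n_clusters=3,
        n_ensemble=3,
        learning_rate=1e-2,
        tau_rate=2e-3,
        max_iters=600,
        early_stop_patience=200,
        hidden_layers=(16, 16),
        seed=0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
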