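import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rtpred import pipeline
from rtpred.dlm import DlmConfig
from rtpred.synthetic_data import GeneratorConfig, gen_library

settings.register_profile(
    "suite", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bench_linear():
    """Full-size benchmark under the pure-linear latent map (no cluster offsets)."""
    return pipeline.train_benchmark(
        GeneratorConfig(nonlinearity="linear", cluster_rt_sd=0.0, seed=101),
        DlmConfig(seed=11),
        split_seed=42,
    )


@pytest.fixture(scope="session")
def bench_default():
    """Full-size benchmark under the default generator (nonlinearity + offsets)."""
    return pipeline.train_benchmark(
        GeneratorConfig(seed=202), DlmConfig(seed=12), split_seed=43
    )


@pytest.fixture(scope="session")
def knn_cmp(bench_default):
    """Naive k-NN vs network comparison across similarity strata."""
    return pipeline.compare_knn_vs_dlm(bench_default, reps=1000, seed=3)


@pytest.fixture(scope="session")
def small_library():
    """A 400-molecule library for unit tests that do not need the full benchmark."""
    return gen_library(GeneratorConfig(n_molecules=400, n_clusters=40, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
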