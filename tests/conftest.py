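import numpy as np
import pytest

from sumpc import SimConfig, simulate_dataset, summarize_raw


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_subjects=300, n_snps=150, seed=11)


@pytest.fixture(scope="session")
def small_raw(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def exact_panel(small_raw):
    return summarize_raw(small_raw, mode="exact")


@pytest.fixture(scope="session")
def hwe_panel(small_raw):
    return summarize_raw(small_raw, mode="hwe")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
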