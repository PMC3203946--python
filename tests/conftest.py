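import numpy as np
import pytest

from hibernaseq.simulate import SimulationConfig, generate_reference, generate_run


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=11, n_tissues=1, n_timepoints=6, n_genes=30, reads_per_sample=300,
        duplicate_rate=0.2, mito_fraction={"heart": 0.2}, junction_read_fraction=0.1,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_reference(small_config)


@pytest.fixture(scope="session")
def small_run(small_config):
    """One generated run (truth, reads) shared read-only across tests."""
    return generate_run(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
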