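import pytest

from matchloci import AnalysisConfig, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """1,000-gene noise-free dataset with default category fractions."""
    return simulate_dataset(SimulationConfig(n_genes=1000, seed=1))


@pytest.fixture()
def default_config():
    return AnalysisConfig()
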