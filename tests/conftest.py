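import pytest

from graftflow.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A miniature heterograft design: quick enough for unit tests while
    keeping the default homology (85%) and mobility ordering."""
    return SimulationConfig(
        n_genes=30, gene_length_range=(300, 600), ortholog_identity=0.85,
        n_mobile=6, mobility_factor_near=0.05, mobility_factor_far=0.01,
        reads_per_sample=2000, read_length=100, error_rate=0.005,
        n_replicates=2, seed=7)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config)
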