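import pytest

from dupscape import paralogs
from dupscape.synthdata import SimulationConfig, simulate_genome


SMALL_CONFIG = dict(
    n_chromosomes=2,
    chromosome_lengths=[6_000_000, 6_000_000],
    n_background_genes=80,
    n_tandem_arrays=4,
    array_size_min=3,
    array_size_max=6,
    n_proximal=4,
    n_dispersed=3,
    protein_length=120,
)


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated genome shared by fast unit tests."""
    return simulate_genome(SimulationConfig(seed=7, **SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_sim_identity(small_sim):
    return paralogs.identity_matrix(small_sim.proteins)


@pytest.fixture(scope="session")
def default_sim():
    """A genome at the simulator's default study conditions."""
    return simulate_genome(SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def default_sim_clusters(default_sim):
    matrix = paralogs.identity_matrix(default_sim.proteins)
    clusters = paralogs.cluster_paralogs(default_sim.proteins, matrix=matrix)
    return matrix, clusters
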