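import pytest
from hypothesis import settings

from provirome.synthetic import SimulationConfig, generate_world

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_world():
    """The standard study conditions: 8 genera, 32 hosts, 64 viruses."""
    return generate_world(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def alpha95_world():
    """Strongly host-adapted world used for host-prediction recovery."""
    return generate_world(SimulationConfig(seed=2, alpha_host_mixing=0.95))


@pytest.fixture(scope="session")
def large_vc_world():
    """World whose virus clusters clear the >10-member matrix cut."""
    return generate_world(
        SimulationConfig(seed=5, hosts_per_genus=6, viruses_per_host=2)
    )


@pytest.fixture(scope="session")
def small_world():
    """Cheap world for structural checks."""
    return generate_world(
        SimulationConfig(
            seed=7, n_genera=4, hosts_per_genus=2, genome_length_bp=60_000,
            viral_length_range_bp=(5_000, 15_000),
        )
    )
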