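import pytest
from hypothesis import HealthCheck, settings

import geneconnectome as gc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def triangle_net():
    """A-B (w=2), B-C (w=3), A-C (w=10): shortest A->C goes through B."""
    return gc.build_network([("A", "B", 0.5), ("B", "C", 1 / 3), ("A", "C", 0.1)])


@pytest.fixture
def chain_net():
    """Unit-weight chain A-B-C-D."""
    return gc.build_network([("A", "B", 1.0), ("B", "C", 1.0), ("C", "D", 1.0)])


@pytest.fixture
def two_clique_net():
    """Two disjoint 5-cliques: cross-clique pairs are unreachable."""
    net, _ = gc.generate_network(
        10, 2, p_within=1.0, p_between=0.0, conf_range=(0.8, 0.999), seed=3
    )
    return net


@pytest.fixture(scope="session")
def small_world():
    """A modest planted world shared by read-only tests."""
    params = gc.WorldParams(
        n_genes=150, n_modules=3, p_within=0.4, p_between=0.02,
        disease_modules=(0,), n_core=20, n_holdout=5, n_terms=30,
    )
    return gc.generate_world(params, seed=11)


@pytest.fixture(scope="session")
def default_world():
    """The documented default study conditions (500 genes, 5 modules)."""
    return gc.generate_world(seed=0)
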