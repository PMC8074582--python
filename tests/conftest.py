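import networkx as nx
import pytest

from netblocks.synthetic import fixture_graphs


@pytest.fixture(scope="session")
def fixtures() -> dict[str, nx.Graph]:
    return fixture_graphs()


@pytest.fixture
def triangle(fixtures):
    return fixtures["triangle"]


@pytest.fixture
def k4(fixtures):
    return fixtures["K4"]


@pytest.fixture
def path10(fixtures):
    return fixtures["path10"]


@pytest.fixture
def star10(fixtures):
    return fixtures["star10"]


def er_graph(n: int, p: float, seed: int) -> nx.Graph:
    """Seeded Erdos-Renyi graph with string node labels."""
    return nx.relabel_nodes(nx.gnp_random_graph(n, p, seed=seed), str)


def connected_er_graph(n: int, p: float, seed: int) -> nx.Graph:
    from netblocks.graphcore import largest_component

    return largest_component(er_graph(n, p, seed))
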