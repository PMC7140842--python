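import networkx as nx
import pytest

from netprops.genesets import GeneSet, map_to_network
from netprops.network_io import Network


@pytest.fixture
def path4() -> Network:
    """Path graph a-b-c-d."""
    return Network.from_edges([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def triangle() -> Network:
    return Network.from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def star5() -> Network:
    """Star with center c and 4 leaves."""
    return Network.from_edges([("c", f"l{i}") for i in range(4)])


@pytest.fixture
def two_cliques_bridge() -> Network:
    """Two 5-cliques joined by a single bridge edge a0-b0."""
    edges = []
    for prefix in ("a", "b"):
        for i in range(5):
            for j in range(i + 1, 5):
                edges.append((f"{prefix}{i}", f"{prefix}{j}"))
    edges.append(("a0", "b0"))
    return Network.from_edges(edges)


def er_network(n: int, p: float, seed: int) -> Network:
    g = nx.gnp_random_graph(n, p, seed=seed)
    return Network.from_edges(
        ((f"n{a:02d}", f"n{b:02d}") for a, b in g.edges()),
        isolated=(f"n{v:02d}" for v in g if g.degree(v) == 0),
    )


def mapped(net: Network, genes, name: str = "S"):
    return map_to_network(GeneSet(name=name, genes=frozenset(genes)), net)


@pytest.fixture
def er20() -> Network:
    return er_network(20, 0.2, seed=7)
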