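import random

import networkx as nx
import pytest

from ideaspark import SemanticNetwork, default_stoplist, toy_network_T1


@pytest.fixture(scope="session")
def t1() -> SemanticNetwork:
    return toy_network_T1()


@pytest.fixture(scope="session")
def stoplist() -> set[str]:
    return default_stoplist()


def random_connected_network(rng: random.Random, max_n: int = 40) -> SemanticNetwork:
    """A random connected word graph for property tests."""
    n = rng.randint(2, max_n)
    p = rng.uniform(0.08, 0.5)
    while True:
        g = nx.gnp_random_graph(n, p, seed=rng.randrange(2**31))
        if nx.is_connected(g):
            break
    g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
    return SemanticNetwork(g, metadata={"lcc": True})
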