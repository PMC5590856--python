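import networkx as nx
import numpy as np
import pytest

from evogeo import PPINetwork, SyntheticSpec, random_geometric_network
from evogeo.synthetic import toy_fixture


def random_connected_network(n: int, p: float, rng: np.random.Generator
                             ) -> PPINetwork:
    """Erdos-Renyi graph resampled until connected (test helper)."""
    ids = [f"n{i:03d}" for i in range(n)]
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            return PPINetwork.from_id_pairs(
                [(ids[a], ids[b]) for a, b in g.edges()], extra_nodes=ids)


@pytest.fixture(scope="session")
def toy():
    return toy_fixture()


@pytest.fixture(scope="session")
def geo_small():
    """~120-node geometric network and its maximum component."""
    from evogeo import max_connected_component

    net, coords = random_geometric_network(
        SyntheticSpec(n=120, geo_dim=2, radius=0.17, seed=11))
    return max_connected_component(net), coords
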