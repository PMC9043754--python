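import numpy as np
import pytest

from dynhypernet.hypernet import Hyperedge, Hypernetwork


def make_hypernetwork(edge_sets, node_count=None):
    """Hand-built hypernetwork from iterables of node ids (seed = min node)."""
    edge_sets = [frozenset(e) for e in edge_sets]
    if node_count is None:
        node_count = max((max(e) for e in edge_sets), default=0) + 1
    edges = [
        Hyperedge(nodes=e, seed=min(e), lambda1=0.1) for e in edge_sets if len(e) >= 2
    ]
    return Hypernetwork(node_count=node_count, hyperedges=edges)


def random_hypernetwork(rng, n_nodes=8, n_edges=6):
    """Random hypergraph: distinct hyperedges of size >= 2."""
    sets = set()
    for _ in range(n_edges):
        size = int(rng.integers(2, min(n_nodes, 5) + 1))
        sets.add(frozenset(rng.choice(n_nodes, size=size, replace=False).tolist()))
    return make_hypernetwork(sets, node_count=n_nodes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_edge_net():
    """The worked example: hyperedges {a,b,c} and {b,c,d} on nodes 0..3."""
    return make_hypernetwork([{0, 1, 2}, {1, 2, 3}])
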