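"""The five hypergraph node metrics against independent brute-force oracles."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from conftest import make_hypernetwork, random_hypernetwork
from dynhypernet.hypermetrics import (
    DegenerateNodeError,
    hcc1,
    hcc2,
    hcc3,
    hccpn,
    hccpn_pair,
    metric_table,
    shortest_path_avg,
)


# ---- independent oracles (set comprehensions + networkx BFS) ----------------

def oracle_all(edges, n_nodes, v):
    """All five metrics for node v by direct enumeration."""
    edges = [set(e) for e in edges]
    S = [e for e in edges if v in e]
    N = set().union(*S) - {v} if S else set()
    npairs = len(N) * (len(N) - 1) // 2

    h1 = (
        sum(
            1
            for u, t in combinations(sorted(N), 2)
            if any(u in e and t in e and v not in e for e in edges)
        ) / npairs
        if npairs else 0.0
    )
    h2 = (
        sum(
            1
            for u, t in combinations(sorted(N), 2)
            if any({u, t, v} <= e for e in edges)
        ) / npairs
        if npairs else 0.0
    )
    h3 = (
        (sum(len(e) - 1 for e in S) - len(N)) / (len(N) * (len(S) - 1))
        if len(S) >= 2 and N else 0.0
    )

    def star(u):
        return {i for i, e in enumerate(edges) if u in e}

    hp = (
        float(np.mean([
            len(star(u) & star(v)) / np.sqrt(len(star(u)) * len(star(v)))
            for u in sorted(N)
        ]))
        if N else 0.0
    )

    G = nx.Graph()
    G.add_nodes_from(range(n_nodes))
    for e in edges:
        G.add_edges_from(combinations(sorted(e), 2))
    lengths = nx.single_source_shortest_path_length(G, v)
    del lengths[v]
    sp = float(np.mean(list(lengths.values()))) if lengths else 0.0
    return h1, h2, h3, hp, sp


def enumerate_hypergraphs(n_nodes, max_edges):
    """Every hypergraph with <= max_edges distinct hyperedges of size >= 2."""
    all_edges = [
        frozenset(c)
        for size in range(2, n_nodes + 1)
        for c in combinations(range(n_nodes), size)
    ]
    for k in range(max_edges + 1):
        for sel in combinations(all_edges, k):
            yield list(sel)


# ---- worked examples ---------------------------------------------------------

def test_single_hyperedge_row():
    H = make_hypernetwork([{0, 1, 2}])
    assert hcc1(H, 0) == 0.0
    assert hcc2(H, 0) == 1.0
    assert hcc3(H, 0) == 0.0
    assert hccpn(H, 0) == 1.0
    assert shortest_path_avg(H, 0) == 1.0
    row = metric_table(H).values[0]
    assert np.allclose(row, [0, 1, 0, 1, 1])


def test_two_edge_worked_example(two_edge_net):
    H = two_edge_net  # {a,b,c}, {b,c,d} with a,b,c,d = 0,1,2,3
    assert hcc1(H, 0) == 1.0  # pair (b,c) covered by {b,c,d}
    assert hcc1(H, 1) == 0.0
    assert hcc3(H, 1) == pytest.approx(1 / 3)
    assert hccpn_pair(H, 1, 2) == pytest.approx(1.0)  # 2/sqrt(2*2)
    assert hccpn(H, 0) == pytest.approx(1 / np.sqrt(2))
    assert shortest_path_avg(H, 0) == pytest.approx(4 / 3)


def test_hcc3_overlap_extremes():
    from dynhypernet.hypernet import Hyperedge, Hypernetwork

    # disjoint edges through v (no shared neighbours) -> 0
    assert hcc3(make_hypernetwork([{0, 1}, {0, 2}]), 0) == 0.0
    # repeated edges over the same neighbour set -> maximal overlap 1
    twin = Hypernetwork(
        node_count=3,
        hyperedges=[
            Hyperedge(nodes=frozenset({0, 1, 2}), seed=0, lambda1=0.1),
            Hyperedge(nodes=frozenset({0, 1, 2}), seed=1, lambda1=0.2),
        ],
    )
    assert hcc3(twin, 0) == 1.0


def test_chain_shortest_path():
    H = make_hypernetwork([{0, 1}, {1, 2}, {2, 3}])
    assert shortest_path_avg(H, 0) == pytest.approx(2.0)  # (1+2+3)/3


def test_degenerate_policy_and_strict_mode():
    H = make_hypernetwork([{0, 1}], node_count=3)
    assert hcc1(H, 2) == 0.0 and hccpn(H, 2) == 0.0 and shortest_path_avg(H, 2) == 0.0
    with pytest.raises(DegenerateNodeError):
        hcc1(H, 2, strict=True)
    with pytest.raises(DegenerateNodeError):
        hcc3(H, 0, strict=True)
    with pytest.raises(DegenerateNodeError):
        shortest_path_avg(H, 0, strict=True)  # node 2 unreachable
    tab = metric_table(H)
    assert tab.flags[2].all()


def test_empty_hypernetwork_all_zero_flagged():
    H = make_hypernetwork([], node_count=4)
    tab = metric_table(H)
    assert np.allclose(tab.values, 0.0) and tab.flags.all()


def test_literal_variants():
    H = make_hypernetwork([{0, 1, 2}, {1, 2, 3}])
    assert hcc3(H, 1, variant="literal2x") == pytest.approx(2 / 3)
    assert hccpn_pair(H, 1, 2, denom="literal-product") == pytest.approx(0.5)


# ---- oracle equivalence and properties ---------------------------------------

def test_exhaustive_small_hypergraphs_match_oracle():
    for edges in enumerate_hypergraphs(4, 2):
        H = make_hypernetwork(edges, node_count=4)
        for v in range(4):
            ref = oracle_all(edges, 4, v)
            got = (hcc1(H, v), hcc2(H, v), hcc3(H, v), hccpn(H, v),
                   shortest_path_avg(H, v))
            assert np.allclose(got, ref), (edges, v)


def test_random_hypergraphs_match_oracle(rng):
    for _ in range(30):
        H = random_hypernetwork(rng, n_nodes=8, n_edges=6)
        edges = H.edge_sets()
        v = int(rng.integers(8))
        ref = oracle_all(edges, 8, v)
        got = (hcc1(H, v), hcc2(H, v), hcc3(H, v), hccpn(H, v),
               shortest_path_avg(H, v))
        assert np.allclose(got, ref)


def test_metric_table_consistent_with_single_node_ops(rng):
    H = random_hypernetwork(rng, n_nodes=7, n_edges=5)
    tab = metric_table(H)
    for v in range(7):
        assert np.allclose(
            tab.values[v],
            [hcc1(H, v), hcc2(H, v), hcc3(H, v), hccpn(H, v),
             shortest_path_avg(H, v)],
        )


def test_ranges_on_random_instances(rng):
    for _ in range(100):
        H = random_hypernetwork(rng, n_nodes=8, n_edges=6)
        tab = metric_table(H).values
        assert (tab[:, :4] >= 0).all() and (tab[:, :4] <= 1 + 1e-12).all()
        sp = tab[:, 4]
        assert ((sp == 0) | (sp >= 1)).all()


def test_node_relabeling_equivariance(rng):
    H = random_hypernetwork(rng, n_nodes=6, n_edges=5)
    perm = rng.permutation(6)
    relabeled = make_hypernetwork(
        [frozenset(int(perm[v]) for v in e) for e in H.edge_sets()], node_count=6
    )
    tab = metric_table(H).values
    tab_p = metric_table(relabeled).values
    for v in range(6):
        assert np.allclose(tab[v], tab_p[perm[v]])
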