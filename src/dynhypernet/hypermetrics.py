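"""Node-level hypergraph metrics.

Five local topological properties are computed per hypernetwork node:

* ``hcc1`` — fraction of unordered neighbour pairs of v co-contained in some
  hyperedge that excludes v (interactions that cannot be artifacts of v).
* ``hcc2`` — fraction of neighbour pairs co-contained in a hyperedge together
  with v itself.
* ``hcc3`` — extra-overlap ratio of the hyperedges through v: how much the
  edges in S(v) re-cover the same neighbours beyond the first visit.
* ``hccpn`` — mean over neighbours u of the pair coefficient
  |S(u) ∩ S(v)| / sqrt(|S(u)| |S(v)|), the geometric-mean compromise between
  the max- and min-criterion overlap ratios.
* ``shortest_path_avg`` — mean minimal number of hyperedges traversed from v
  to each reachable peer (binary, unweighted hypergraph distance).

Degenerate nodes (too few neighbours or incident edges for the denominator)
yield 0 with a per-cell flag under the default policy; ``strict=True`` raises
instead.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .hypernet import Hypernetwork

__all__ = [
    "DegenerateNodeError",
    "NodeNeighborhood",
    "NodeMetricTable",
    "neighborhood",
    "hcc1",
    "hcc2",
    "hcc3",
    "hccpn",
    "shortest_path_avg",
    "metric_table",
    "METRIC_NAMES",
]

METRIC_NAMES = ("hcc1", "hcc2", "hcc3", "hccpn", "sp")


class DegenerateNodeError(ValueError):
    """Raised in strict mode when a metric's denominator is undefined."""


@dataclass
class NodeNeighborhood:
    """N(v): co-members of some hyperedge with v; S(v): hyperedges through v."""

    neighbors: frozenset[int]
    edges: tuple[frozenset[int], ...]


def neighborhood(H: Hypernetwork, v: int) -> NodeNeighborhood:
    edges = tuple(e for e in H.edge_sets() if v in e)
    nbrs: set[int] = set()
    for e in edges:
        nbrs |= e
    nbrs.discard(v)
    return NodeNeighborhood(neighbors=frozenset(nbrs), edges=edges)


def _pairs(nodes: frozenset[int]) -> list[tuple[int, int]]:
    ns = sorted(nodes)
    return [(ns[i], ns[j]) for i in range(len(ns)) for j in range(i + 1, len(ns))]


def hcc1(H: Hypernetwork, v: int, strict: bool = False) -> float:
    """Neighbour pairs of v covered by a hyperedge *excluding* v, normalised
    by C(|N(v)|, 2)."""
    nb = neighborhood(H, v)
    n = len(nb.neighbors)
    if n < 2:
        if strict:
            raise DegenerateNodeError(f"node {v}: fewer than 2 neighbors")
        return 0.0
    others = [e for e in H.edge_sets() if v not in e]
    hits = sum(
        1 for u, t in _pairs(nb.neighbors) if any(u in e and t in e for e in others)
    )
    return hits / (n * (n - 1) / 2)


def hcc2(H: Hypernetwork, v: int, strict: bool = False) -> float:
    """Neighbour pairs of v co-contained in a hyperedge *with* v, normalised
    by C(|N(v)|, 2)."""
    nb = neighborhood(H, v)
    n = len(nb.neighbors)
    if n < 2:
        if strict:
            raise DegenerateNodeError(f"node {v}: fewer than 2 neighbors")
        return 0.0
    hits = sum(
        1 for u, t in _pairs(nb.neighbors) if any(u in e and t in e for e in nb.edges)
    )
    return hits / (n * (n - 1) / 2)


def hcc3(
    H: Hypernetwork, v: int, variant: str = "normalized", strict: bool = False
) -> float:
    """Extra-overlap ratio of the hyperedges through v.

    ``normalized`` (default): (sum_{e in S(v)} (|e|-1) - |N(v)|) /
    (|N(v)| (|S(v)|-1)), which lies in [0, 1]; ``literal2x`` doubles the
    numerator (the printed-formula factor 2, which can exceed 1).
    """
    if variant not in ("normalized", "literal2x"):
        raise ValueError("variant must be 'normalized' or 'literal2x'")
    nb = neighborhood(H, v)
    n = len(nb.neighbors)
    s = len(nb.edges)
    if s < 2 or n == 0:
        if strict:
            raise DegenerateNodeError(f"node {v}: |S(v)|<2 or no neighbors")
        return 0.0
    num = sum(len(e) - 1 for e in nb.edges) - n
    if variant == "literal2x":
        num *= 2
    return num / (n * (s - 1))


def hccpn_pair(H: Hypernetwork, u: int, v: int, denom: str = "geometric") -> float:
    """Pairwise coefficient |S(u) ∩ S(v)| / sqrt(|S(u)||S(v)|) (geometric) or
    / (|S(u)||S(v)|) (literal-product)."""
    if denom not in ("geometric", "literal-product"):
        raise ValueError("denom must be 'geometric' or 'literal-product'")
    su = set(neighborhood(H, u).edges)
    sv = set(neighborhood(H, v).edges)
    if not su or not sv:
        return 0.0
    inter = len(su & sv)
    prod = len(su) * len(sv)
    return inter / np.sqrt(prod) if denom == "geometric" else inter / prod


def hccpn(
    H: Hypernetwork, v: int, denom: str = "geometric", strict: bool = False
) -> float:
    """Mean pairwise coefficient over the neighbours of v."""
    nb = neighborhood(H, v)
    if not nb.neighbors:
        if strict:
            raise DegenerateNodeError(f"node {v}: no neighbors")
        return 0.0
    vals = [hccpn_pair(H, u, v, denom=denom) for u in sorted(nb.neighbors)]
    return float(np.mean(vals))


def _bfs_hyperedge_distances(H: Hypernetwork, v: int) -> dict[int, int]:
    """Minimum number of hyperedges traversed from v to each reachable node."""
    adj: dict[int, set[int]] = {}
    for e in H.edge_sets():
        for u in e:
            adj.setdefault(u, set()).update(e - {u})
    dist = {v: 0}
    q = deque([v])
    while q:
        u = q.popleft()
        for t in adj.get(u, ()):
            if t not in dist:
                dist[t] = dist[u] + 1
                q.append(t)
    del dist[v]
    return dist


def shortest_path_avg(H: Hypernetwork, v: int, strict: bool = False) -> float:
    """Mean hyperedge-hop distance from v to its reachable peers.

    Isolated nodes yield 0; unreachable peers are excluded from the mean.
    ``strict=True`` errors when any peer is unreachable (including isolation).
    """
    dist = _bfs_hyperedge_distances(H, v)
    reachable = len(dist)
    if strict and reachable < H.node_count - 1:
        raise DegenerateNodeError(f"node {v}: hypergraph disconnected at this node")
    if reachable == 0:
        return 0.0
    return float(np.mean(list(dist.values())))


def metric_table(
    H: Hypernetwork,
    hcc3_variant: str = "normalized",
    hccpn_denom: str = "geometric",
) -> "NodeMetricTable":
    """Assemble the M x 5 per-node metric table with degeneracy flags."""
    M = H.node_count
    values = np.zeros((M, 5))
    flags = np.zeros((M, 5), dtype=bool)
    for v in range(M):
        nb = neighborhood(H, v)
        n, s = len(nb.neighbors), len(nb.edges)
        values[v, 0] = hcc1(H, v)
        values[v, 1] = hcc2(H, v)
        values[v, 2] = hcc3(H, v, variant=hcc3_variant)
        values[v, 3] = hccpn(H, v, denom=hccpn_denom)
        values[v, 4] = shortest_path_avg(H, v)
        flags[v, 0] = flags[v, 1] = n < 2
        flags[v, 2] = s < 2 or n == 0
        flags[v, 3] = n == 0
        flags[v, 4] = n == 0
    return NodeMetricTable(values=values, flags=flags)


@dataclass
class NodeMetricTable:
    """Per-subject M x 5 matrix, columns [HCC1, HCC2, HCC3, HCCPN, SP];
    ``flags`` marks cells zeroed by the degenerate-denominator policy."""

    values: np.ndarray
    flags: np.ndarray
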