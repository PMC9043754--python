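"""Kernel construction and alignment-maximising fusion.

Subjects are embedded twice: an RBF kernel on the selected local-metric
features (vector kernel) and a linear kernel on Weisfeiler-Lehman subtree
similarities between each subject's clique-expanded hypernetwork and the
discriminative subgraph patterns (graph kernel).  The two base kernels are
fused as K_f = sum_l mu_l K_l where mu maximises the kernel-target alignment
<K_f, yy'>_F / ||K_f||_F, solved in closed form as mu = F^{-1} b / ||F^{-1} b||
with b_l = <K_l, yy'>_F and F_mn = <K_m, K_n>_F.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.metrics.pairwise import rbf_kernel

from .featselect import DiscriminativeSet
from .hypernet import Hypernetwork

__all__ = [
    "KernelBundle",
    "WLCache",
    "clique_expand",
    "wl_feature_maps",
    "wl_kernel",
    "subject_graph_features",
    "base_kernels",
    "align_weights",
    "combine_kernels",
]


def clique_expand(obj: Hypernetwork | frozenset[int] | set[int]) -> nx.Graph:
    """Expand hyperedges into cliques over their nodes.

    A single node set becomes one clique; a hypernetwork becomes the union of
    its hyperedge cliques (set semantics: no multi-edges, no self-loops).
    Every node is labelled by its global connection id, shared across
    subjects, so WL label counts are comparable between graphs.
    """
    G = nx.Graph()
    if isinstance(obj, Hypernetwork):
        edge_sets = obj.edge_sets()
    else:
        if not obj:
            raise ValueError("node set must be non-empty")
        edge_sets = [frozenset(obj)]
    for es in edge_sets:
        ns = sorted(es)
        G.add_nodes_from(ns)
        G.add_edges_from(
            (ns[i], ns[j]) for i in range(len(ns)) for j in range(i + 1, len(ns))
        )
    for v in G.nodes:
        G.nodes[v]["label"] = v
    return G


def wl_feature_maps(
    graphs: list[nx.Graph], h: int = 3
) -> list[Counter]:
    """Label-count feature maps summed over WL iterations 0..h.

    Labels are compressed through one dictionary shared by all graphs in the
    batch, so inner products of the returned Counters are WL subtree kernel
    values.  Refinement hashes the (own label, sorted neighbour multiset)
    pair.  All h refinement rounds are carried out: stopping a graph early
    once its own partition stabilises would freeze it in an older code space
    and silently drop cross-graph label matches, so no such shortcut is taken.
    """
    cache = WLCache(h)
    return [cache.feature_map(G) for G in graphs]


class WLCache:
    """Shared label-compression dictionary for WL feature maps.

    Each structural key (initial label, or a (label, sorted neighbour labels)
    pair) receives a stable integer code on first encounter, so maps computed
    one graph at a time against the same cache are mutually consistent —
    identical to a joint batch computation — and repeated graphs cost nothing
    when memoised by the caller.
    """

    def __init__(self, h: int = 3) -> None:
        if h < 0:
            raise ValueError("h must be >= 0")
        self.h = h
        self._compress: dict = {}

    def _code(self, key) -> int:
        d = self._compress
        if key not in d:
            d[key] = len(d)
        return d[key]

    def feature_map(self, G: nx.Graph) -> Counter:
        lbl = {v: self._code(("init", G.nodes[v]["label"])) for v in G.nodes}
        feats = Counter(lbl.values())
        for _ in range(self.h):
            lbl = {
                v: self._code(
                    (lbl[v], tuple(sorted(lbl[u] for u in G.neighbors(v))))
                )
                for v in G.nodes
            }
            feats += Counter(lbl.values())
        return feats


def _dot(a: Counter, b: Counter) -> float:
    if len(b) < len(a):
        a, b = b, a
    return float(sum(v * b[k] for k, v in a.items()))


def wl_kernel(G1: nx.Graph, G2: nx.Graph, h: int = 3) -> float:
    """WL subtree kernel: sum over iterations i = 0..h of the inner product of
    the two graphs' label-count vectors."""
    if h < 0:
        raise ValueError("h must be >= 0")
    f1, f2 = wl_feature_maps([G1, G2], h)
    return _dot(f1, f2)


def subject_graph_features(
    H: Hypernetwork | nx.Graph,
    patterns: DiscriminativeSet | list,
    h: int = 3,
    cache: "WLCache | None" = None,
) -> np.ndarray:
    """WL similarity of one subject's hypernetwork to every pattern in Omega*.

    Entry i is wl_kernel(clique_expand(g_i), clique_expand(H), h); the vector
    is then L2-normalised (an all-zero vector is left as zero).  All graphs in
    the call share one label-compression dictionary, so the entries are
    mutually consistent WL kernel values.
    """
    if isinstance(patterns, DiscriminativeSet):
        plist = [p.nodes for p in patterns.patterns]
    else:
        plist = [p.nodes if hasattr(p, "nodes") else frozenset(p) for p in patterns]
    if not plist:
        raise ValueError("pattern set must be non-empty")
    cache = cache if cache is not None else WLCache(h)
    subject_graph = H if isinstance(H, nx.Graph) else clique_expand(H)
    subj_map = cache.feature_map(subject_graph)
    vec = np.array(
        [_dot(cache.feature_map(clique_expand(p)), subj_map) for p in plist]
    )
    nrm = np.linalg.norm(vec)
    if nrm > 0:
        vec = vec / nrm
    return vec


def base_kernels(
    localfeat: np.ndarray,
    graphfeat: np.ndarray,
    gamma: float,
    standardize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Vector (RBF) and graph (linear) base kernels, trace-normalised to n.

    ``localfeat`` rows are subjects' selected local features (z-scored here
    unless the caller already standardised with training statistics);
    ``graphfeat`` rows are the normalised WL similarity vectors.  ``gamma``
    is a dimensionless per-feature bandwidth: the kernel is
    ``exp(-gamma * ||x - z||^2 / p)`` with ``p`` the feature count, so one
    gamma grid spans the useful range whatever the width of the selected
    feature space.
    """
    X = np.asarray(localfeat, float)
    Gf = np.asarray(graphfeat, float)
    if X.shape[0] != Gf.shape[0]:
        raise ValueError("feature matrices must share subject order")
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    K_vec = rbf_kernel(X, gamma=gamma / max(X.shape[1], 1))
    K_graph = Gf @ Gf.T
    n = X.shape[0]
    for K in (K_vec, K_graph):
        tr = np.trace(K)
        if tr > 0:
            K *= n / tr
    return K_vec, K_graph


def align_weights(K_list: list[np.ndarray], y: np.ndarray) -> np.ndarray:
    """Closed-form alignment-maximising fusion weights, ||mu||_2 = 1.

    b_l = <K_l, yy'>_F, F_mn = <K_m, K_n>_F, mu = F^{-1} b / ||F^{-1} b||
    (pseudo-inverse when F is singular).  Components may be negative.
    """
    y = np.asarray(y, float).ravel()
    Ky = np.outer(y, y)
    b = np.array([float(np.sum(K * Ky)) for K in K_list])
    if np.allclose(b, 0):
        raise ValueError("all base kernels are uninformative (zero alignment)")
    F = np.array([[float(np.sum(Km * Kn)) for Kn in K_list] for Km in K_list])
    try:
        mu = np.linalg.solve(F, b)
    except np.linalg.LinAlgError:
        mu = np.linalg.pinv(F) @ b
    if not np.isfinite(mu).all() or np.allclose(mu, 0):
        mu = np.linalg.pinv(F) @ b
    nrm = np.linalg.norm(mu)
    if nrm == 0:
        raise ValueError("degenerate kernel Gram matrix; cannot determine weights")
    return mu / nrm


def combine_kernels(K_list: list[np.ndarray], mu: np.ndarray) -> np.ndarray:
    """Fused kernel K_f = sum_l mu_l K_l."""
    mu = np.asarray(mu, float)
    if not np.isclose(np.linalg.norm(mu), 1.0, atol=1e-8):
        raise ValueError("fusion weights must have unit L2 norm")
    return sum(m * K for m, K in zip(mu, K_list))


@dataclass
class KernelBundle:
    """Base kernels, fusion weights and the fused kernel for one cohort."""

    kernels: list[np.ndarray]
    y: np.ndarray
    mu: np.ndarray
    fused: np.ndarray
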