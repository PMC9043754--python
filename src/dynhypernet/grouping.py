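"""Grouping of functional connections for the sparse group LASSO penalty.

Connections whose relevant time series behave similarly are clustered into k
non-overlapping groups by PAM-style k-medoids with k-means++ (D-squared)
seeding and multi-restart selection; the grouping defines the group structure
of the regression penalty in the hypernetwork construction stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .dynconn import RelevantSeriesMatrix

__all__ = ["ConnectionGrouping", "connection_distances", "kmedoids_cluster"]


@dataclass
class ConnectionGrouping:
    """Partition of the M connection nodes into k groups.

    ``assignments[m]`` is the group id of node m; ``medoids[g]`` is the node
    serving as the centre of group g; ``cost`` is the total distance of every
    node to its medoid.
    """

    assignments: np.ndarray
    medoids: np.ndarray
    cost: float
    seed: int

    @property
    def k(self) -> int:
        return len(self.medoids)

    def group_members(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.assignments == g) for g in range(self.k)]


def connection_distances(
    cts: RelevantSeriesMatrix | np.ndarray, metric: str = "euclidean"
) -> np.ndarray:
    """Pairwise distances between relevant-series columns (M x M, symmetric).

    ``metric='euclidean'`` is the default; ``metric='correlation'`` gives the
    1 - r distance between columns.
    """
    values = cts.values if isinstance(cts, RelevantSeriesMatrix) else np.asarray(cts)
    if metric not in ("euclidean", "correlation"):
        raise ValueError("metric must be 'euclidean' or 'correlation'")
    D = squareform(pdist(values.T, metric=metric))
    # pdist 'correlation' returns nan for constant columns; treat them as
    # maximally dissimilar to everything but themselves.
    if np.isnan(D).any():
        D = np.nan_to_num(D, nan=2.0)
        np.fill_diagonal(D, 0.0)
    return D


def _dsq_seeding(dist: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ D^2 rule applied to medoids: first centre uniform, each later
    centre drawn with probability proportional to squared distance to the
    nearest chosen centre."""
    M = dist.shape[0]
    medoids = [int(rng.integers(M))]
    d_near = dist[medoids[0]].copy()
    for _ in range(1, k):
        w = d_near**2
        total = w.sum()
        if total == 0:
            # all remaining points coincide with a centre; pick lowest
            # unused index for determinism
            unused = [m for m in range(M) if m not in medoids]
            medoids.append(unused[0])
        else:
            medoids.append(int(rng.choice(M, p=w / total)))
        d_near = np.minimum(d_near, dist[medoids[-1]])
    return np.array(sorted(medoids))


def _assign(dist: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    sub = dist[:, medoids]
    a = np.argmin(sub, axis=1)  # argmin takes the first minimum: lowest index wins
    cost = float(sub[np.arange(len(a)), a].sum())
    return a, cost


def _pam_swap(
    dist: np.ndarray, medoids: np.ndarray, max_iter: int
) -> tuple[np.ndarray, float]:
    """Greedy PAM: repeatedly apply the single best improving medoid swap."""
    M = dist.shape[0]
    medoids = medoids.copy()
    _, cost = _assign(dist, medoids)
    for _ in range(max_iter):
        sub = dist[:, medoids]
        order = np.argsort(sub, axis=1, kind="stable")
        d1 = sub[np.arange(M), order[:, 0]]
        d2 = sub[np.arange(M), order[:, 1]] if len(medoids) > 1 else np.full(M, np.inf)
        near = order[:, 0]
        best_delta, best_swap = 0.0, None
        in_medoids = np.zeros(M, bool)
        in_medoids[medoids] = True
        candidates = np.flatnonzero(~in_medoids)
        for gi in range(len(medoids)):
            affected = near == gi
            base = np.where(affected, d2, d1)  # cost if medoid gi removed
            for c in candidates:
                new_cost = float(np.minimum(base, dist[:, c]).sum())
                delta = new_cost - cost
                if delta < best_delta - 1e-12:
                    best_delta, best_swap = delta, (gi, c)
        if best_swap is None:
            break
        gi, c = best_swap
        medoids[gi] = c
        medoids = np.array(sorted(medoids))
        _, cost = _assign(dist, medoids)
    return medoids, cost


def kmedoids_cluster(
    dist: np.ndarray,
    k: int,
    seed: int,
    restarts: int = 10,
    max_iter: int = 100,
) -> ConnectionGrouping:
    """Cluster M points into k groups; return the best of ``restarts`` runs.

    Each restart seeds medoids with the D^2 rule and refines them by greedy PAM
    swaps; the restart with minimal total within-cluster distance wins (ties:
    the earliest restart).  Deterministic given ``seed``.
    """
    dist = np.asarray(dist, dtype=float)
    M = dist.shape[0]
    if not 1 <= k <= M:
        raise ValueError(f"k must be in [1, {M}], got {k}")
    rng = np.random.default_rng(seed)
    best: ConnectionGrouping | None = None
    for _ in range(restarts):
        medoids = _dsq_seeding(dist, k, rng)
        medoids, cost = _pam_swap(dist, medoids, max_iter)
        if best is None or cost < best.cost - 1e-12:
            assignments, cost = _assign(dist, medoids)
            best = ConnectionGrouping(
                assignments=assignments, medoids=medoids, cost=cost, seed=seed
            )
    assert best is not None
    return best
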