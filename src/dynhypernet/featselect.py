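"""Discriminative feature selection.

Two feature families are selected between the two subject groups:

* local hypergraph metrics — per-column two-sample Kolmogorov-Smirnov statistic
  with a permutation null, corrected jointly by Benjamini-Hochberg FDR;
* subgraph patterns (hyperedge node-sets) — frequent-scoring feature selection
  (FSFS): each distinct pattern is scored by the absolute between-group
  frequency difference and the top-t patterns per group are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .hypernet import Hypernetwork

__all__ = [
    "SelectionResult",
    "SubgraphPattern",
    "DiscriminativeSet",
    "ks_statistic",
    "ks_perm_test",
    "bh_fdr",
    "select_local_features",
    "fsfs_score",
    "fsfs_select",
]

logger = logging.getLogger(__name__)

EXACT_ENUM_LIMIT = 10_000


def ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample KS statistic D = sup_t |ECDF_x(t) - ECDF_y(t)| (tie-safe)."""
    x = np.sort(np.asarray(x, float))
    y = np.sort(np.asarray(y, float))
    grid = np.union1d(x, y)
    fx = np.searchsorted(x, grid, side="right") / len(x)
    fy = np.searchsorted(y, grid, side="right") / len(y)
    return float(np.abs(fx - fy).max())


def _perm_stats(
    pooled: np.ndarray, n1: int, assignments: np.ndarray
) -> np.ndarray:
    """KS statistics of ``pooled`` under each row of boolean ``assignments``
    (True marks membership of the first sample).  Vectorised and tie-safe:
    D is the running |F1 - F2| gap evaluated at the last occurrence of each
    distinct pooled value."""
    n = len(pooled)
    n2 = n - n1
    order = np.argsort(pooled, kind="stable")
    sv = pooled[order]
    valid = np.empty(n, dtype=bool)
    valid[:-1] = sv[1:] != sv[:-1]
    valid[-1] = True
    Z = np.where(assignments[:, order], 1.0 / n1, -1.0 / n2)
    gaps = np.abs(np.cumsum(Z, axis=1))[:, valid]
    return gaps.max(axis=1)


def ks_perm_test(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "permutation",
) -> tuple[float, float]:
    """Two-sample KS test; p-value from the permutation null.

    All C(n1+n2, n1) group splits are enumerated exactly when their number is
    at most 10^4; otherwise ``n_perm`` random splits are drawn and
    p = (1 + #{D* >= D}) / (1 + n_perm).  ``method='asymptotic'`` uses the
    classical KS limiting distribution instead.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    d = ks_statistic(x, y)
    if method == "asymptotic":
        from scipy.stats import ks_2samp

        return d, float(ks_2samp(x, y, mode="asymp").pvalue)
    if method != "permutation":
        raise ValueError("method must be 'permutation' or 'asymptotic'")
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    total = comb(n, n1)
    if total <= EXACT_ENUM_LIMIT:
        A = np.zeros((total, n), dtype=bool)
        for r, idx in enumerate(combinations(range(n), n1)):
            A[r, list(idx)] = True
        stats = _perm_stats(pooled, n1, A)
        p = float(np.mean(stats >= d - 1e-12))
    else:
        rng = np.random.default_rng(seed)
        A = np.zeros((n_perm, n), dtype=bool)
        for r in range(n_perm):
            A[r, rng.permutation(n)[:n1]] = True
        stats = _perm_stats(pooled, n1, A)
        p = (1.0 + float(np.sum(stats >= d - 1e-12))) / (1.0 + n_perm)
    return d, p


def bh_fdr(p: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rule: reject the hypotheses whose sorted
    rank i satisfies p_(i) <= i*q/m, up to the largest such i."""
    p = np.asarray(p, float)
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    thresh = q * np.arange(1, m + 1) / m
    below = p[order] <= thresh
    mask = np.zeros(m, dtype=bool)
    if below.any():
        kmax = int(np.max(np.flatnonzero(below)))
        mask[order[: kmax + 1]] = True
    return mask


@dataclass
class SelectionResult:
    """Per-column KS p-values and the joint BH-FDR decision."""

    p_values: np.ndarray
    statistics: np.ndarray
    selected: np.ndarray  # boolean mask over columns
    q: float

    @property
    def selected_columns(self) -> np.ndarray:
        return np.flatnonzero(self.selected)


def select_local_features(
    features: np.ndarray,
    labels: np.ndarray,
    q: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> SelectionResult:
    """Column-wise KS permutation tests followed by joint BH-FDR correction.

    ``labels`` holds 'positive'/'negative' (or boolean with True = positive).
    One shared permutation set is drawn for all columns.  Constant columns get
    p = 1 (logged).  The surviving columns define the vector-kernel feature
    space.
    """
    F = np.asarray(features, float)
    lab = _as_bool_labels(labels)
    if not lab.any() or lab.all():
        raise ValueError("both groups must be non-empty")
    n, m = F.shape
    n1 = int(lab.sum())
    idx = np.concatenate([np.flatnonzero(lab), np.flatnonzero(~lab)])
    total = comb(n, n1)
    if total <= EXACT_ENUM_LIMIT:
        A = np.zeros((total, n), dtype=bool)
        for r, c in enumerate(combinations(range(n), n1)):
            A[r, list(c)] = True
        exact = True
    else:
        rng = np.random.default_rng(seed)
        A = np.zeros((n_perm, n), dtype=bool)
        for r in range(n_perm):
            A[r, rng.permutation(n)[:n1]] = True
        exact = False
    obs_row = np.zeros((1, n), dtype=bool)
    obs_row[0, :n1] = True
    stats = np.zeros(m)
    pvals = np.ones(m)
    for j in range(m):
        col = F[idx, j]
        if np.ptp(col) == 0:
            logger.debug("column %d is constant; p set to 1", j)
            continue
        d = float(_perm_stats(col, n1, obs_row)[0])
        null = _perm_stats(col, n1, A)
        stats[j] = d
        if exact:
            pvals[j] = float(np.mean(null >= d - 1e-12))
        else:
            pvals[j] = (1.0 + float(np.sum(null >= d - 1e-12))) / (1.0 + len(A))
    return SelectionResult(
        p_values=pvals, statistics=stats, selected=bh_fdr(pvals, q), q=q
    )


def _as_bool_labels(labels) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.dtype == bool:
        return lab
    return lab == "positive"


@dataclass(frozen=True)
class SubgraphPattern:
    """A hyperedge node-set with its per-group occurrence frequencies."""

    nodes: frozenset[int]
    fq_pos: float
    fq_neg: float

    @property
    def score(self) -> float:
        """Discriminative score S = |fq_pos - fq_neg|."""
        return abs(self.fq_pos - self.fq_neg)

    @property
    def source_group(self) -> str:
        """Group with the higher frequency (ties go to positive)."""
        return "positive" if self.fq_pos >= self.fq_neg else "negative"


@dataclass
class DiscriminativeSet:
    """Omega* = top-t1 positive-side plus top-t2 negative-side patterns,
    each side sorted by descending score."""

    positive: list[SubgraphPattern]
    negative: list[SubgraphPattern]
    t1: int
    t2: int

    @property
    def patterns(self) -> list[SubgraphPattern]:
        return self.positive + self.negative

    def __len__(self) -> int:
        return len(self.positive) + len(self.negative)


def _contains(H: Hypernetwork, pattern: frozenset[int], mode: str) -> bool:
    if mode == "exact":
        return any(e == pattern for e in H.edge_sets())
    return any(pattern <= e for e in H.edge_sets())


def fsfs_score(
    pattern: frozenset[int] | set[int],
    cohort: list[Hypernetwork],
    labels,
    containment: str = "exact",
) -> SubgraphPattern:
    """Score one pattern: the fraction of subjects per group whose hyperedge
    set contains it (node-set equality by default)."""
    pattern = frozenset(pattern)
    if not pattern:
        raise ValueError("pattern must be non-empty")
    lab = _as_bool_labels(labels)
    pos = [H for H, is_pos in zip(cohort, lab) if is_pos]
    neg = [H for H, is_pos in zip(cohort, lab) if not is_pos]
    fq_pos = np.mean([_contains(H, pattern, containment) for H in pos]) if pos else 0.0
    fq_neg = np.mean([_contains(H, pattern, containment) for H in neg]) if neg else 0.0
    return SubgraphPattern(nodes=pattern, fq_pos=float(fq_pos), fq_neg=float(fq_neg))


def fsfs_select(
    cohort: list[Hypernetwork],
    labels,
    t1: int = 36,
    t2: int = 36,
    containment: str = "exact",
) -> DiscriminativeSet:
    """Frequent-scoring feature selection over all distinct hyperedge node-sets.

    Each candidate is assigned to the group where it is more frequent, sides
    are sorted by descending score (ties: smaller pattern, then lexicographic
    node order), and the top t1 / t2 are kept.  Invariant to subject and
    hyperedge order.
    """
    lab = _as_bool_labels(labels)
    if not lab.any() or lab.all():
        raise ValueError("cohort must contain both groups")
    candidates: set[frozenset[int]] = set()
    subject_sets = [set(H.edge_sets()) for H in cohort]
    for es in subject_sets:
        candidates.update(es)
    n_pos = int(lab.sum())
    n_neg = int((~lab).sum())
    if containment == "exact":
        # one pass over every subject's distinct hyperedge sets
        pos_counts: dict[frozenset[int], int] = {}
        neg_counts: dict[frozenset[int], int] = {}
        for es, is_pos in zip(subject_sets, lab):
            bucket = pos_counts if is_pos else neg_counts
            for g in es:
                bucket[g] = bucket.get(g, 0) + 1
        scored = [
            SubgraphPattern(
                nodes=g,
                fq_pos=pos_counts.get(g, 0) / n_pos,
                fq_neg=neg_counts.get(g, 0) / n_neg,
            )
            for g in candidates
        ]
    else:
        scored = [fsfs_score(g, cohort, lab, containment) for g in candidates]

    def sort_key(sp: SubgraphPattern):
        return (-sp.score, len(sp.nodes), tuple(sorted(sp.nodes)))

    pos_side = sorted((s for s in scored if s.source_group == "positive"), key=sort_key)
    neg_side = sorted((s for s in scored if s.source_group == "negative"), key=sort_key)
    if len(pos_side) < t1 or len(neg_side) < t2:
        logger.info(
            "fewer candidates than requested (pos %d/%d, neg %d/%d); taking all",
            len(pos_side), t1, len(neg_side), t2,
        )
    return DiscriminativeSet(
        positive=pos_side[:t1], negative=neg_side[:t2], t1=t1, t2=t2
    )
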