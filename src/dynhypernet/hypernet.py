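"""High-order functional hypernetwork construction via sparse group LASSO.

Every connection node m is regressed, over the sliding-window axis, on all
other connections' relevant time series with the sparse group LASSO objective

    ||y - X a||^2 + lambda1 ||a||_1 + lambda2 sum_i ||a_{G_i}||_2

(no 1/2 factor on the quadratic term).  The nonzero support of the solution,
together with the seed node itself, forms one hyperedge; sweeping a ladder of
lambda1 values and all M seed nodes yields the subject's hypernetwork.

Columns of the design matrix and the response are centred and scaled to unit
L2 norm before solving, so the 0.1-0.9 ladder thresholds correlations on an
absolute scale and is comparable across subjects; only the support is used
downstream, so the coefficient scale is immaterial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dynconn import RelevantSeriesMatrix
from .grouping import ConnectionGrouping

__all__ = [
    "SGLassoConfig",
    "Hyperedge",
    "Hypernetwork",
    "sglasso_objective",
    "sglasso_solve",
    "build_hypernetwork",
]

DEFAULT_LAMBDA1_LADDER = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))


@dataclass(frozen=True)
class SGLassoConfig:
    """Solver and ladder settings for hypernetwork construction.

    ``lambda1_set`` is the ascending ladder of within-group sparsity weights;
    ``lambda2`` controls group-level sparsity.  ``group_weighting`` chooses a
    literal (unweighted) group penalty or sqrt-of-group-size weights.
    """

    lambda1_set: tuple[float, ...] = DEFAULT_LAMBDA1_LADDER
    lambda2: float = 0.4
    group_weighting: str = "literal"
    tol: float = 1e-5
    max_iter: int = 1000
    support_eps: float = 1e-6

    def __post_init__(self) -> None:
        lam = tuple(float(v) for v in self.lambda1_set)
        if not lam:
            raise ValueError("lambda1_set must be non-empty")
        if any(v < 0 for v in lam) or any(b <= a for a, b in zip(lam, lam[1:])):
            raise ValueError("lambda1_set must be strictly ascending and >= 0")
        if self.lambda2 < 0:
            raise ValueError("lambda2 must be >= 0")
        if self.group_weighting not in ("literal", "sqrt-size"):
            raise ValueError("group_weighting must be 'literal' or 'sqrt-size'")
        object.__setattr__(self, "lambda1_set", lam)


@dataclass(frozen=True)
class Hyperedge:
    """A hyperedge: the seed connection plus the support of its regression."""

    nodes: frozenset[int]
    seed: int
    lambda1: float

    def __post_init__(self) -> None:
        if self.seed not in self.nodes:
            raise ValueError("seed must belong to its hyperedge")


@dataclass
class Hypernetwork:
    """Node set of M connections plus the hyperedges built over them."""

    node_count: int
    hyperedges: list[Hyperedge]
    subject_id: str = ""
    node_labels: list[str] = field(default_factory=list)

    def edge_sets(self) -> list[frozenset[int]]:
        return [e.nodes for e in self.hyperedges]


def _group_lists(groups: ConnectionGrouping | np.ndarray, p: int) -> list[np.ndarray]:
    if isinstance(groups, ConnectionGrouping):
        assignments = groups.assignments
    else:
        assignments = np.asarray(groups)
    if len(assignments) != p:
        raise ValueError(
            f"group assignment length {len(assignments)} != column count {p}"
        )
    return [np.flatnonzero(assignments == g) for g in np.unique(assignments)]


def sglasso_objective(
    X: np.ndarray,
    y: np.ndarray,
    alpha: np.ndarray,
    groups: ConnectionGrouping | np.ndarray,
    lambda1: float,
    lambda2: float,
    group_weights: np.ndarray | None = None,
) -> float:
    """Value of ||y - Xa||^2 + lambda1 ||a||_1 + lambda2 sum w_i ||a_Gi||_2."""
    gl = _group_lists(groups, X.shape[1])
    w = np.ones(len(gl)) if group_weights is None else group_weights
    r = y - X @ alpha
    gval = sum(wi * np.linalg.norm(alpha[g]) for wi, g in zip(w, gl))
    return float(r @ r + lambda1 * np.abs(alpha).sum() + lambda2 * gval)


def _prox(v: np.ndarray, t1: float, t2w: np.ndarray, gl: list[np.ndarray]) -> np.ndarray:
    """Proximal operator of t1*||.||_1 + sum_i t2w_i*||._Gi||_2 (groups disjoint):
    elementwise soft-threshold, then groupwise L2 shrinkage."""
    u = np.sign(v) * np.maximum(np.abs(v) - t1, 0.0)
    for t2, g in zip(t2w, gl):
        if t2 <= 0:
            continue
        nrm = np.linalg.norm(u[g])
        if nrm <= t2:
            u[g] = 0.0
        else:
            u[g] *= 1.0 - t2 / nrm
    return u


def sglasso_solve(
    X: np.ndarray,
    y: np.ndarray,
    groups: ConnectionGrouping | np.ndarray,
    lambda1: float,
    lambda2: float,
    cfg: SGLassoConfig | None = None,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Minimise the sparse group LASSO objective by accelerated proximal gradient.

    Monotone FISTA: the best iterate (lowest objective) seen is returned, so the
    objective at the solution never exceeds the objective at zero.  Non-convergence
    within ``cfg.max_iter`` issues a warning and returns the best iterate.
    """
    cfg = cfg or SGLassoConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]} entries")
    p = X.shape[1]
    gl = _group_lists(groups, p)
    gw = (
        np.sqrt([len(g) for g in gl])
        if cfg.group_weighting == "sqrt-size"
        else np.ones(len(gl))
    )
    return _solve_gram(
        X.T @ X, X.T @ y, float(y @ y), gl, gw, lambda1, lambda2, cfg,
        x0=x0, warn=True,
    )


def _standardize_columns(values: np.ndarray) -> np.ndarray:
    """Centre each column and scale it to unit L2 norm (constant columns -> 0)."""
    Z = values - values.mean(axis=0)
    nrm = np.linalg.norm(Z, axis=0)
    nz = nrm > 0
    Z[:, nz] /= nrm[nz]
    return Z


def build_hypernetwork(
    cts: RelevantSeriesMatrix,
    groups: ConnectionGrouping,
    cfg: SGLassoConfig | None = None,
    subject_id: str = "",
) -> Hypernetwork:
    """Sweep every seed node over the lambda1 ladder and assemble hyperedges.

    For seed m the design matrix is the standardized relevant-series matrix with
    column m zeroed; the hyperedge is {m} plus the columns whose coefficient
    magnitude exceeds ``support_eps``.  Singleton hyperedges (empty support) are
    dropped and duplicate node-sets are deduplicated, keeping the first
    (lowest seed, then smallest lambda1) provenance.
    """
    cfg = cfg or SGLassoConfig()
    M = cts.n_connections
    if M < 3:
        raise ValueError("need at least 3 connection nodes")
    Z = _standardize_columns(cts.values.copy())
    gl = _group_lists(groups, M)
    gw = (
        np.sqrt([len(g) for g in gl])
        if cfg.group_weighting == "sqrt-size"
        else np.ones(len(gl))
    )
    G_full = Z.T @ Z
    edges: list[Hyperedge] = []
    seen: set[frozenset[int]] = set()
    for m in range(M):
        y = Z[:, m]
        if not np.any(y):
            continue  # constant relevant series: no regression target
        # Gram of the design with column m zeroed
        G = G_full.copy()
        G[m, :] = 0.0
        G[:, m] = 0.0
        c = G_full[:, m].copy()
        c[m] = 0.0
        a = None
        for lam1 in cfg.lambda1_set:
            a = _solve_gram(G, c, 1.0, gl, gw, lam1, cfg.lambda2, cfg, x0=a)
            support = np.flatnonzero(np.abs(a) > cfg.support_eps)
            nodes = frozenset(support.tolist()) | {m}
            if len(nodes) < 2 or nodes in seen:
                continue
            seen.add(nodes)
            edges.append(Hyperedge(nodes=nodes, seed=m, lambda1=float(lam1)))
    return Hypernetwork(
        node_count=M,
        hyperedges=edges,
        subject_id=subject_id,
        node_labels=cts.connection_index.labels(),
    )


def _solve_gram(
    G: np.ndarray,
    c: np.ndarray,
    yy: float,
    gl: list[np.ndarray],
    gw: np.ndarray,
    lambda1: float,
    lambda2: float,
    cfg: SGLassoConfig,
    x0: np.ndarray | None = None,
    warn: bool = False,
) -> np.ndarray:
    """Monotone FISTA on the Gram form: minimises
    yy - 2 c'a + a'Ga + lambda1 ||a||_1 + lambda2 sum w_i ||a_Gi||_2."""
    p = G.shape[0]
    L = 2.0 * float(np.linalg.eigvalsh(G)[-1]) if p else 1.0
    if L <= 0:
        return np.zeros(p)
    step = 1.0 / L
    t1 = step * lambda1
    t2w = step * lambda2 * gw

    def full_obj(a: np.ndarray) -> float:
        gval = sum(wi * np.linalg.norm(a[g]) for wi, g in zip(gw, gl))
        return yy - 2.0 * (c @ a) + a @ (G @ a) + lambda1 * np.abs(a).sum() + lambda2 * gval

    a = np.zeros(p) if x0 is None else np.asarray(x0, float).copy()
    a_prev = a.copy()
    tk = 1.0
    best_a, best_f = a.copy(), full_obj(a)
    f0 = full_obj(np.zeros(p))
    if f0 < best_f:
        best_a, best_f = np.zeros(p), f0
    prev_f, last_f = best_f, best_f
    converged = False
    check_every = 20
    for it in range(cfg.max_iter):
        tk_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        z = a + ((tk - 1.0) / tk_next) * (a - a_prev)
        grad = 2.0 * (G @ z - c)
        a_prev, a = a, _prox(z - step * grad, t1, t2w, gl)
        tk = tk_next
        f = full_obj(a)
        if f > last_f:  # adaptive restart: drop momentum when objective rises
            tk = 1.0
            a_prev = a.copy()
        last_f = f
        if f < best_f:
            best_a, best_f = a.copy(), f
        if (it + 1) % check_every == 0:
            denom = max(abs(prev_f), 1e-12)
            if prev_f - best_f < cfg.tol * denom:
                converged = True
                break
            prev_f = best_f
    if warn and not converged:
        warnings.warn(
            f"sparse group LASSO did not converge in {cfg.max_iter} iterations; "
            "returning best iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    return best_a
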