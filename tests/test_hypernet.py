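import numpy as np
import pytest

from dynhypernet.dynconn import ConnectionIndex, RelevantSeriesMatrix, WindowSpec
from dynhypernet.grouping import ConnectionGrouping
from dynhypernet.hypernet import (
    SGLassoConfig,
    build_hypernetwork,
    sglasso_objective,
    sglasso_solve,
)


def grouping(assignments):
    assignments = np.asarray(assignments)
    medoids = np.array([np.flatnonzero(assignments == g)[0] for g in np.unique(assignments)])
    return ConnectionGrouping(assignments=assignments, medoids=medoids, cost=0.0, seed=0)


def reference_ista(X, y, groups, lam1, lam2, n_iter=100_000):
    """Independent slow solver: plain proximal gradient with a conservative
    fixed step, run to high precision."""
    G = np.asarray(groups)
    p = X.shape[1]
    L = 2.0 * np.linalg.norm(X, 2) ** 2
    step = 0.5 / L
    a = np.zeros(p)
    for _ in range(n_iter):
        grad = 2.0 * X.T @ (X @ a - y)
        v = a - step * grad
        v = np.sign(v) * np.maximum(np.abs(v) - step * lam1, 0.0)
        for g in np.unique(G):
            idx = G == g
            nrm = np.linalg.norm(v[idx])
            thr = step * lam2
            v[idx] = 0.0 if nrm <= thr else v[idx] * (1 - thr / nrm)
        if np.max(np.abs(v - a)) < 1e-12:
            a = v
            break
        a = v
    return a


def kkt_residual(X, y, a, groups, lam1, lam2):
    """Maximal violation of the subgradient optimality conditions of the
    objective ||y-Xa||^2 + lam1||a||_1 + lam2 sum ||a_G||."""
    G = np.asarray(groups)
    g_full = 2.0 * X.T @ (X @ a - y)
    worst = 0.0
    for gid in np.unique(G):
        idx = np.flatnonzero(G == gid)
        ag = a[idx]
        gg = g_full[idx]
        if np.allclose(ag, 0):
            # need s with |s_i|<=lam1 s.t. ||gg + s|| <= lam2
            shrunk = np.sign(gg) * np.maximum(np.abs(gg) - lam1, 0.0)
            worst = max(worst, max(0.0, np.linalg.norm(shrunk) - lam2))
        else:
            dir_g = lam2 * ag / np.linalg.norm(ag)
            for i, (ai, gi, di) in enumerate(zip(ag, gg, dir_g)):
                if ai != 0:
                    worst = max(worst, abs(gi + lam1 * np.sign(ai) + di))
                else:
                    worst = max(worst, max(0.0, abs(gi) - lam1))
    return worst


def test_huge_l1_penalty_gives_zero(rng):
    X = rng.standard_normal((10, 6))
    y = rng.standard_normal(10)
    lam1 = 2.0 * np.abs(X.T @ y).max() + 1.0
    a = sglasso_solve(X, y, np.zeros(6, int), lam1, 0.0)
    assert np.allclose(a, 0.0)


def test_orthogonal_response_gives_zero(rng):
    X = np.vstack([np.eye(3), -np.eye(3)])  # columns sum to zero pairs
    y = np.ones(6)
    assert np.allclose(X.T @ y, 0.0)
    a = sglasso_solve(X, y, np.array([0, 0, 1]), 0.3, 0.2)
    assert np.allclose(a, 0.0)


def test_zero_penalty_matches_least_squares(rng):
    X = rng.standard_normal((5, 2))
    y = rng.standard_normal(5)
    a = sglasso_solve(X, y, np.zeros(2, int), 0.0, 0.0,
                      SGLassoConfig(tol=1e-14, max_iter=20000))
    ref, *_ = np.linalg.lstsq(X, y, rcond=None)
    assert np.allclose(a, ref, atol=1e-5)


def test_matches_reference_solver_and_kkt(rng):
    for trial in range(5):
        X = rng.standard_normal((8, 6))
        y = rng.standard_normal(8)
        groups = np.array([0, 0, 0, 1, 1, 1])
        lam1, lam2 = 0.5, 0.4
        a = sglasso_solve(X, y, groups, lam1, lam2,
                          SGLassoConfig(tol=1e-12, max_iter=20000))
        ref = reference_ista(X, y, groups, lam1, lam2)
        f = sglasso_objective(X, y, a, groups, lam1, lam2)
        f_ref = sglasso_objective(X, y, ref, groups, lam1, lam2)
        assert f <= f_ref + 1e-4
        assert kkt_residual(X, y, a, groups, lam1, lam2) < 1e-3


def test_objective_never_worse_than_zero(rng):
    X = rng.standard_normal((12, 8))
    y = rng.standard_normal(12)
    groups = np.array([0, 0, 1, 1, 2, 2, 3, 3])
    for lam1, lam2 in [(0.1, 0.1), (1.0, 2.0), (5.0, 0.0)]:
        a = sglasso_solve(X, y, groups, lam1, lam2)
        f = sglasso_objective(X, y, a, groups, lam1, lam2)
        f0 = sglasso_objective(X, y, np.zeros(8), groups, lam1, lam2)
        assert f <= f0 + 1e-10


def test_dimension_mismatch_raises(rng):
    with pytest.raises(ValueError, match="rows"):
        sglasso_solve(rng.standard_normal((5, 3)), rng.standard_normal(4),
                      np.zeros(3, int), 0.1, 0.1)


def make_cts(values):
    values = np.asarray(values, float)
    M = values.shape[1]
    N = int((1 + np.sqrt(1 + 8 * M)) / 2)
    return RelevantSeriesMatrix(
        values=values, window_spec=WindowSpec(2, 1), connection_index=ConnectionIndex(N)
    )


def test_white_noise_high_lambda_gives_near_empty_network(rng):
    cts = make_cts(rng.standard_normal((100, 10)))
    g = grouping(np.arange(10) % 3)
    H = build_hypernetwork(cts, g, SGLassoConfig(lambda1_set=(0.9,), lambda2=0.4))
    assert len(H.hyperedges) <= 1


def test_copied_column_forms_hyperedge_at_smallest_lambda(rng):
    vals = rng.standard_normal((60, 8))
    vals[:, 1] = vals[:, 0]
    cts = make_cts(vals)
    g = grouping(np.arange(8) % 2)
    H = build_hypernetwork(cts, g)
    seeded0 = [e for e in H.hyperedges if e.seed == 0]
    assert seeded0 and min(e.lambda1 for e in seeded0) == pytest.approx(0.1)
    first = min(seeded0, key=lambda e: e.lambda1)
    assert 1 in first.nodes


def test_absurd_lambda_ladder_gives_no_hyperedges(rng):
    cts = make_cts(rng.standard_normal((30, 6)))
    H = build_hypernetwork(cts, grouping(np.zeros(6, int)),
                           SGLassoConfig(lambda1_set=(1000.0,)))
    assert H.hyperedges == []


def test_hyperedge_invariants_and_dedup(rng):
    cts = make_cts(rng.standard_normal((40, 10)))
    H = build_hypernetwork(cts, grouping(np.arange(10) % 4))
    seen = set()
    for e in H.hyperedges:
        assert e.seed in e.nodes and len(e.nodes) >= 2
        assert all(0 <= v < 10 for v in e.nodes)
        assert e.nodes not in seen
        seen.add(e.nodes)


def test_edge_count_nonincreasing_in_lambda_on_average(rng):
    ladder = (0.2, 0.5, 0.8)
    counts = np.zeros(3)
    for _ in range(20):
        cts = make_cts(rng.standard_normal((25, 10)))
        g = grouping(np.arange(10) % 3)
        for li, lam in enumerate(ladder):
            H = build_hypernetwork(cts, g, SGLassoConfig(lambda1_set=(lam,)))
            counts[li] += len(H.hyperedges)
    assert counts[0] >= counts[1] >= counts[2]
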