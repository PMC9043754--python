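from itertools import combinations

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from conftest import make_hypernetwork
from dynhypernet.featselect import (
    bh_fdr,
    fsfs_score,
    fsfs_select,
    ks_perm_test,
    ks_statistic,
    select_local_features,
)


def ks_oracle(x, y):
    """ECDF sup-difference evaluated on a dense grid of pooled values."""
    grid = np.sort(np.concatenate([x, y]))
    fx = np.array([(x <= t).mean() for t in grid])
    fy = np.array([(y <= t).mean() for t in grid])
    return np.abs(fx - fy).max()


def test_ks_statistic_basic_and_oracle(rng):
    assert ks_statistic([0, 0, 0], [1, 1, 1]) == 1.0
    x = rng.standard_normal(9)
    assert ks_perm_test(x, x, seed=0)[0] == 0.0
    for _ in range(20):
        x = rng.choice([0.0, 0.5, 1.0, 2.0], size=7)  # heavy ties
        y = rng.standard_normal(5)
        assert ks_statistic(x, y) == pytest.approx(ks_oracle(x, y))


def test_identical_samples_p_one(rng):
    x = rng.standard_normal(5)
    d, p = ks_perm_test(x, x.copy(), seed=1)
    assert d == 0.0 and p == 1.0


def test_exact_enumeration_small_samples(rng):
    x = np.array([0.1, 0.7, 1.3])
    y = np.array([0.4, 2.0, 2.5])
    d, p = ks_perm_test(x, y, seed=0)
    # exhaustive oracle over all C(6,3)=20 splits
    pooled = np.concatenate([x, y])
    stats = []
    for idx in combinations(range(6), 3):
        mask = np.zeros(6, bool)
        mask[list(idx)] = True
        stats.append(ks_oracle(pooled[mask], pooled[~mask]))
    p_ref = np.mean(np.array(stats) >= d - 1e-12)
    assert p == pytest.approx(p_ref)
    assert d == pytest.approx(ks_oracle(x, y))


def test_ks_rejects_tiny_samples():
    with pytest.raises(ValueError):
        ks_perm_test([1.0], [1.0, 2.0])


def test_bh_fdr_worked_examples():
    sel = bh_fdr(np.array([0.01, 0.02, 0.03, 0.5]), q=0.05)
    assert sel.tolist() == [True, True, True, False]
    assert not bh_fdr(np.ones(10), q=0.05).any()
    assert bh_fdr(np.array([0.0, 0.9, 0.8]), q=0.05)[0]


def brute_force_step_up(p, q):
    m = len(p)
    order = np.argsort(p, kind="stable")
    kmax = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            kmax = i
    mask = np.zeros(m, bool)
    mask[order[:kmax]] = True
    return mask


def test_bh_fdr_against_brute_force_and_statsmodels(rng):
    for _ in range(200):
        m = int(rng.integers(1, 30))
        p = rng.uniform(size=m) ** rng.uniform(0.3, 3)
        q = float(rng.choice([0.01, 0.05, 0.1, 0.2]))
        mine = bh_fdr(p, q)
        assert np.array_equal(mine, brute_force_step_up(p, q))
        ref, *_ = multipletests(p, alpha=q, method="fdr_bh")
        assert np.array_equal(mine, ref)


def test_select_local_features_finds_separated_column(rng):
    n = 12
    labels = np.array(["positive"] * 6 + ["negative"] * 6)
    F = rng.standard_normal((n, 8))
    F[:6, 3] += 10.0  # perfectly separated column
    res = select_local_features(F, labels, q=0.05, n_perm=500, seed=0)
    assert 3 in res.selected_columns
    assert res.p_values[3] == res.p_values.min()


def test_select_constant_column_p_one(rng):
    labels = np.array(["positive"] * 5 + ["negative"] * 5)
    F = rng.standard_normal((10, 4))
    F[:, 2] = 7.0
    res = select_local_features(F, labels, seed=0)
    assert res.p_values[2] == 1.0 and 2 not in res.selected_columns


def test_select_null_calibration(rng):
    """Under exchangeable groups the fraction of small p-values is ~uniform."""
    labels = np.array(["positive"] * 8 + ["negative"] * 8)
    hits = []
    for trial in range(20):
        F = rng.standard_normal((16, 25))
        res = select_local_features(F, labels, q=0.05, n_perm=300, seed=trial)
        hits.append((res.p_values <= 0.05).mean())
    assert np.mean(hits) < 0.15  # near the nominal 5%, far from systematic


def test_fsfs_score_examples():
    pat = frozenset({0, 1})
    pos = [make_hypernetwork([{0, 1}, {2, 3}]) for _ in range(4)]
    neg = [make_hypernetwork([{2, 3}]) for _ in range(4)]
    labels = ["positive"] * 4 + ["negative"] * 4
    sp = fsfs_score(pat, pos + neg, labels)
    assert sp.fq_pos == 1.0 and sp.fq_neg == 0.0 and sp.score == 1.0
    assert sp.source_group == "positive"
    absent = fsfs_score(frozenset({7, 8}), pos + neg, labels)
    assert absent.score == 0.0
    # arithmetic: 0.6 vs 0.2 (5 pos, 5 neg)
    pos5 = [make_hypernetwork([{0, 1}]) for _ in range(3)] + [
        make_hypernetwork([{2, 3}]) for _ in range(2)
    ]
    neg5 = [make_hypernetwork([{0, 1}]) for _ in range(1)] + [
        make_hypernetwork([{2, 3}]) for _ in range(4)
    ]
    sp = fsfs_score(pat, pos5 + neg5, ["positive"] * 5 + ["negative"] * 5)
    assert sp.score == pytest.approx(0.4)


def test_fsfs_select_matches_hand_scoring():
    # 4+4 toy cohort with hand-built hyperedge sets
    pos = [
        make_hypernetwork([{0, 1}, {2, 3, 4}]),
        make_hypernetwork([{0, 1}, {5, 6}]),
        make_hypernetwork([{0, 1}, {2, 3, 4}]),
        make_hypernetwork([{5, 6}]),
    ]
    neg = [
        make_hypernetwork([{5, 6}, {7, 8}]),
        make_hypernetwork([{7, 8}]),
        make_hypernetwork([{5, 6}, {7, 8}]),
        make_hypernetwork([{2, 3, 4}]),
    ]
    labels = ["positive"] * 4 + ["negative"] * 4
    # hand scores: {0,1}: 3/4-0 = 0.75 (pos); {2,3,4}: 2/4-1/4 = 0.25 (pos)
    #              {7,8}: 0-3/4 = 0.75 (neg); {5,6}: 2/4-2/4 = 0 (tie -> pos)
    omega = fsfs_select(pos + neg, labels, t1=2, t2=2)
    assert [sorted(p.nodes) for p in omega.positive] == [[0, 1], [2, 3, 4]]
    assert [round(p.score, 2) for p in omega.positive] == [0.75, 0.25]
    assert [sorted(p.nodes) for p in omega.negative] == [[7, 8]]
    assert omega.negative[0].score == 0.75
    # zero-score tie assigned to positive side, ranked below scored patterns
    all_pos_sets = [sorted(p.nodes) for p in fsfs_select(pos + neg, labels).positive]
    assert all_pos_sets[-1] == [5, 6]


def test_fsfs_select_invariant_to_order():
    pos = [make_hypernetwork([{0, 1}, {2, 3}]), make_hypernetwork([{0, 1}])]
    neg = [make_hypernetwork([{4, 5}]), make_hypernetwork([{4, 5}, {2, 3}])]
    labels = np.array(["positive", "positive", "negative", "negative"])
    a = fsfs_select(pos + neg, labels, t1=3, t2=3)
    perm = [1, 3, 0, 2]
    cohort = pos + neg
    b = fsfs_select([cohort[i] for i in perm], labels[perm], t1=3, t2=3)
    assert [p.nodes for p in a.patterns] == [p.nodes for p in b.patterns]


def test_fsfs_zero_budget_empty():
    pos = [make_hypernetwork([{0, 1}])]
    neg = [make_hypernetwork([{2, 3}])]
    omega = fsfs_select(pos + neg, ["positive", "negative"], t1=0, t2=0)
    assert len(omega) == 0
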