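import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from rarank import (FeatureTable, FilterRanker, ScoreVector, rank_all_filters,
                    rank_from_scores, score_fisher, score_gini,
                    score_hellinger, score_info_gain, score_r_value,
                    score_relief, score_relieff, score_t_test)
from rarank.filters import FILTER_METHODS


def oracle_scores(tbl, method):
    """Loop-based reference scores for any of the eight filters."""
    X, y = tbl.X, tbl.y
    a, b = X[y == 1], X[y == 0]
    if method == "t_test":
        return np.array([oracles.welch_t_abs(a[:, j], b[:, j]) for j in range(tbl.p)])
    if method == "fisher":
        return np.array([oracles.fisher_score(a[:, j], b[:, j]) for j in range(tbl.p)])
    if method == "hellinger":
        return np.array([
            oracles.hellinger_sq(a[:, j].mean(), a[:, j].var(ddof=1),
                                 b[:, j].mean(), b[:, j].var(ddof=1))
            for j in range(tbl.p)])
    if method == "relief":
        return oracles.relieff_scores(X, y, k=1)
    if method == "relieff":
        return oracles.relieff_scores(X, y, k=min(10, min(tbl.n1, tbl.n2) - 1))
    if method == "info_gain":
        return np.array([oracles.best_split_info_gain(X[:, j], y) for j in range(tbl.p)])
    if method == "gini":
        return np.array([oracles.best_split_gini(X[:, j], y) for j in range(tbl.p)])
    return np.array([oracles.r_value(X[:, j], y, k=5, theta=2.5) for j in range(tbl.p)])


@pytest.mark.parametrize("method", FILTER_METHODS)
def test_scorers_match_brute_force_oracle(method, make_table):
    for seed in range(5):
        tbl = make_table(n1=4, n2=6, p=6, shift=0.8, seed=seed)
        got = FilterRanker(method=method).fit(tbl).scores_
        np.testing.assert_allclose(got, oracle_scores(tbl, method), atol=1e-10)


def test_welch_t_textbook_value():
    tbl = FeatureTable(np.array([[1.0], [2], [3], [4], [5], [6]]).repeat(2, axis=1),
                       np.array([1, 1, 1, 0, 0, 0]))
    # Welch t for (1,2,3) vs (4,5,6): |1-4... means 2 vs 5, s²=1 each
    expected = 3.0 / np.sqrt(1 / 3 + 1 / 3)
    np.testing.assert_allclose(score_t_test(tbl).scores, expected, rtol=1e-12)


def test_fisher_closed_form_and_null():
    # means 1 vs 0, each sample variance 0.5 -> score 1/sqrt(1) = 1
    x1 = np.array([0.0, 1.0, 2.0])          # mean 1, var 1
    base = np.array([1.0, 2.0, 3.0])
    tbl = FeatureTable(np.column_stack([np.concatenate([base, base - 2.0]),
                                        np.concatenate([x1, x1])]),
                       np.array([1, 1, 1, 0, 0, 0]))
    got = score_fisher(tbl).scores
    np.testing.assert_allclose(got[0], 2.0 / np.sqrt(2.0), rtol=1e-12)
    assert got[1] == 0.0  # identical class distributions


def test_hellinger_identical_zero_and_separation_limit():
    m = np.array([0.0, 1.0, 2.0, 3.0])
    # identical per-class distributions -> DH2 = 0
    tbl = FeatureTable(np.column_stack([np.concatenate([m, m]),
                                        np.concatenate([m, m + 100.0])]),
                       np.array([1] * 4 + [0] * 4))
    got = score_hellinger(tbl).scores
    np.testing.assert_allclose(got[0], 0.0, atol=1e-12)
    assert got[1] == pytest.approx(2.0, abs=1e-6)  # huge shift -> limit 2
    # direct formula check: mu 0 vs 1, sigma^2 = 1
    expected = oracles.hellinger_sq(0.0, 1.0, 1.0, 1.0)
    assert 0 < expected < 2


def test_hellinger_zero_pooled_variance_names_feature(make_table):
    tbl = make_table(p=3, seed=1)
    X = tbl.X.copy()
    X[:, 1] = 7.0
    bad = FeatureTable(X, tbl.y, ("a", "weird", "c"))
    with pytest.raises(ValueError, match="weird"):
        score_hellinger(bad)


def test_constant_feature_ranked_last_everywhere(make_table):
    tbl = make_table(n1=5, n2=7, p=4, shift=1.5, seed=2)
    X = tbl.X.copy()
    X[:, 2] = 3.14
    tbl = FeatureTable(X, tbl.y)
    for method, sv in [("t_test", score_t_test(tbl)),
                       ("relief", score_relief(tbl)),
                       ("info_gain", score_info_gain(tbl))]:
        assert sv.scores[2] == 0.0, method
        assert rank_from_scores(sv).order[-1] == 2, method
    g = score_gini(tbl)
    parent_gini = 1 - (5 / 12) ** 2 - (7 / 12) ** 2
    assert g.scores[2] == pytest.approx(parent_gini)


def test_relief_single_feature_difference_update():
    # two tight same-class pairs far apart; miss differs by d in feature 0 only
    X = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 0.0], [3.0, 0.0]])
    y = np.array([1, 1, 0, 0])
    s = score_relief(FeatureTable(X, y)).scores
    # scaled feature 0 distance between classes is 1; hit distance 0
    np.testing.assert_allclose(s, [4.0, 0.0])  # each of 4 samples adds 1^2


def test_relieff_k1_equals_relief(make_table):
    tbl = make_table(n1=5, n2=6, p=4, seed=5)
    np.testing.assert_allclose(score_relieff(tbl, k_neighbors=1).scores,
                               score_relief(tbl).scores)


def test_relieff_k_validation(make_table):
    with pytest.raises(ValueError, match="k_neighbors"):
        score_relieff(make_table(), k_neighbors=0)


def test_info_gain_balanced_entropy_and_perfect_split(separable_table):
    tbl = separable_table
    # perfect splitter attains the full dataset entropy
    ig = score_info_gain(tbl).scores
    n1, n = tbl.n1, tbl.n
    ent = -(n1 / n) * np.log2(n1 / n) - (1 - n1 / n) * np.log2(1 - n1 / n)
    assert ig[0] == pytest.approx(ent, rel=1e-12)
    assert ig[1] < ig[0]
    # balanced labels -> Ent(D) = 1 bit (upper bound for any IG)
    bal = FeatureTable(tbl.X[:20], np.array([1] * 10 + [0] * 10))
    assert np.all(score_info_gain(bal).scores <= 1.0 + 1e-12)


def test_gini_balanced_parent_and_pure_split(separable_table):
    g = score_gini(separable_table).scores
    assert g[0] == pytest.approx(0.0, abs=1e-12)  # pure children
    bal = FeatureTable(separable_table.X[:20], np.array([1] * 10 + [0] * 10))
    X = bal.X.copy()
    X[:, 1] = 0.0
    const = FeatureTable(X, bal.y)
    assert score_gini(const).scores[1] == pytest.approx(0.5)  # Gini(D) at balance


def test_r_value_zero_for_disjoint_classes(separable_table):
    r = score_r_value(separable_table).scores
    assert r[0] == 0.0
    assert r[1] > 0.0


def test_r_value_identical_point_multisets_matches_oracle():
    # both classes occupy the same points: outcome driven purely by tie rule
    vals = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 0.0, 1.0, 2.0, 3.0, 4.0])
    y = np.array([1] * 5 + [0] * 5)
    tbl = FeatureTable(np.column_stack([vals, vals]), y)
    got = score_r_value(tbl).scores
    exp = oracles.r_value(vals, y, k=5, theta=2.5)
    np.testing.assert_allclose(got, exp)


@pytest.mark.parametrize(
    "orientation, expected",
    [("larger_better", [1, 2, 0]), ("smaller_better", [0, 2, 1])],
)
def test_rank_from_scores_orientation(orientation, expected):
    sv = ScoreVector(np.array([0.2, 0.9, 0.5]), orientation, "x")
    assert rank_from_scores(sv).order.tolist() == expected


def test_rank_ties_broken_by_index():
    sv = ScoreVector(np.zeros(4), "larger_better", "x")
    assert rank_from_scores(sv).order.tolist() == [0, 1, 2, 3]


def test_rank_handles_infinities():
    sv = ScoreVector(np.array([1.0, np.inf, -np.inf]), "larger_better", "x")
    assert rank_from_scores(sv).order.tolist() == [1, 0, 2]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=12))
def test_rank_is_always_a_permutation_consistent_with_scores(scores):
    sv = ScoreVector(np.array(scores), "larger_better", "x")
    rl = rank_from_scores(sv)
    assert sorted(rl.order.tolist()) == list(range(len(scores)))
    ordered = sv.scores[rl.order]
    assert np.all(ordered[:-1] >= ordered[1:])


@pytest.mark.parametrize("method", FILTER_METHODS)
def test_sample_order_invariance(method, make_table):
    tbl = make_table(n1=5, n2=7, p=5, seed=9)
    perm = np.random.default_rng(0).permutation(tbl.n)
    shuffled = FeatureTable(tbl.X[perm], tbl.y[perm])
    a = FilterRanker(method=method).fit(tbl).scores_
    b = FilterRanker(method=method).fit(shuffled).scores_
    np.testing.assert_allclose(a, b, atol=1e-12)


@pytest.mark.parametrize("method", FILTER_METHODS)
def test_label_swap_invariance(method):
    g = np.random.default_rng(4)
    X = g.normal(0, 1, (12, 4))
    X[:6] += 1.0
    y = np.array([1] * 6 + [0] * 6)
    a = FilterRanker(method=method).fit(FeatureTable(X, y)).scores_
    b = FilterRanker(method=method).fit(FeatureTable(X, 1 - y)).scores_
    np.testing.assert_allclose(a, b, atol=1e-12)


@pytest.mark.parametrize("method", ["t_test", "fisher", "hellinger", "info_gain"])
def test_monotone_in_mean_shift(method):
    g = np.random.default_rng(8)
    noise = g.normal(0, 1, (60, 2))
    prev = -np.inf
    for shift in (0.5, 1.0, 2.0, 4.0, 8.0):
        X = noise.copy()
        X[:30, 0] += shift
        sv = FilterRanker(method=method).fit(
            FeatureTable(X, np.array([1] * 30 + [0] * 30))).scores_
        assert sv[0] >= prev - 1e-12
        prev = sv[0]


def test_rank_all_filters_structure_and_separable_feature(separable_table):
    lists = rank_all_filters(separable_table)
    assert len(lists) == 8
    assert [l.source for l in lists] == list(FILTER_METHODS)
    for l in lists:
        assert sorted(l.order.tolist()) == [0, 1]
        assert l.order[0] == 0  # the separating feature leads everywhere


def test_rank_all_filters_names_failing_method(make_table):
    tbl = make_table(p=3, seed=1)
    X = tbl.X.copy()
    X[:, 0] = 1.0  # constant feature: Hellinger is undefined
    with pytest.raises(RuntimeError, match="hellinger"):
        rank_all_filters(FeatureTable(X, tbl.y))
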