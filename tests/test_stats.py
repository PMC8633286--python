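"""Statistical battery: worked examples, oracles, calibration, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from csfpanel.stats import (bonferroni_adjust, chi_squared, kruskal_dunn,
                            mann_whitney, rank_ancova, roc_auc, spearman)


def test_mann_whitney_exact_enumeration_case():
    res = mann_whitney([1, 2, 3, 4], [10, 11, 12, 13])
    assert res.statistic == 0.0
    assert res.p_raw == pytest.approx(2 / 70)
    assert "exact" in res.method


def test_mann_whitney_identical_multisets():
    res = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
    assert res.p_raw == pytest.approx(1.0)


def test_mann_whitney_tied_data_matches_permutation_oracle():
    rng = np.random.default_rng(1)
    a = rng.integers(0, 6, 15).astype(float)
    b = rng.integers(1, 7, 15).astype(float)
    res = mann_whitney(a, b, mode="normal_approx")
    # permutation oracle on the U statistic
    pooled = np.concatenate([a, b])
    obs = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="asymptotic").statistic
    mu = len(a) * len(b) / 2
    count = 0
    n_perm = 10_000
    for _ in range(n_perm):
        rng.shuffle(pooled)
        u = sps.mannwhitneyu(pooled[:15], pooled[15:],
                             alternative="two-sided",
                             method="asymptotic").statistic
        count += abs(u - mu) >= abs(obs - mu) - 1e-9
    assert res.p_raw == pytest.approx(count / n_perm, abs=0.02)


def test_mann_whitney_rejects_empty_and_bad_mode():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])
    with pytest.raises(ValueError):
        mann_whitney([1], [2], mode="bogus")


def test_kruskal_identical_groups():
    omnibus, _ = kruskal_dunn([1, 2, 3, 1, 2, 3, 1, 2, 3],
                              ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
    assert omnibus.statistic == pytest.approx(0.0)
    assert omnibus.p_raw == pytest.approx(1.0)


def test_kruskal_hand_computed_example():
    vals = [1, 2, 3, 4, 5, 6, 7, 8, 9]
    grp = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
    omnibus, pairwise = kruskal_dunn(vals, grp)
    assert omnibus.statistic == pytest.approx(7.2)
    assert omnibus.p_raw == pytest.approx(0.0273, abs=0.0005)
    assert len(pairwise) == 3
    for pw in pairwise:
        assert pw.p_adjusted >= pw.p_raw
    # extreme pair has the smallest Dunn p
    pmap = {pw.comparison: pw.p_raw for pw in pairwise}
    assert pmap["a vs c"] == min(pmap.values())


def test_kruskal_two_groups_delegates_to_mann_whitney():
    omnibus, pairwise = kruskal_dunn([1, 2, 3, 10, 11, 12],
                                     ["a"] * 3 + ["b"] * 3)
    assert "mann_whitney" in omnibus.method and pairwise == []


def test_kruskal_rejects_empty_group():
    with pytest.raises(ValueError):
        kruskal_dunn([1.0, np.nan], ["a", "b"])


def test_dunn_detects_planted_shift():
    rng = np.random.default_rng(0)
    vals = np.concatenate([rng.normal(0, 1, 30), rng.normal(0, 1, 30),
                           rng.normal(2, 1, 30)])
    grp = np.repeat(["a", "b", "c"], 30)
    _, pairwise = kruskal_dunn(vals, grp)
    pmap = {pw.comparison: pw.p_adjusted for pw in pairwise}
    assert pmap["a vs c"] < 0.01 and pmap["b vs c"] < 0.01
    assert pmap["a vs b"] > 0.05


def test_spearman_monotone_and_sign():
    x = np.arange(1, 20, dtype=float)
    assert spearman(x, x**3).rho == pytest.approx(1.0)
    assert spearman(x, -x).rho == pytest.approx(-1.0)


@settings(derandomize=True, max_examples=30)
@given(st.integers(0, 1000))
def test_spearman_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=20)
    y = rng.normal(size=20)
    r1 = spearman(x, y).rho
    r2 = spearman(np.exp(x), y).rho
    assert r1 == pytest.approx(r2)


def test_spearman_constant_flagged():
    res = spearman([1.0] * 5, [1, 2, 3, 4, 5])
    assert res.degenerate and np.isnan(res.rho)


def test_chi_squared_sex_tables():
    # validation cohort: men/women per group, 4 groups, df 3
    res = chi_squared([[17, 22], [30, 16], [12, 5], [4, 4]])
    assert res.df == 3
    assert res.p_raw == pytest.approx(0.13, abs=0.005)
    # discovery cohort: 3 groups, df 2
    res = chi_squared([[6, 4], [7, 3], [3, 2]])
    assert res.df == 2
    assert res.p_raw == pytest.approx(0.88, abs=0.005)


def test_chi_squared_proportional_and_errors():
    res = chi_squared([[10, 20], [5, 10]])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_raw == pytest.approx(1.0)
    with pytest.raises(ValueError):
        chi_squared([[0, 0], [1, 2]])


def test_roc_perfect_separation_and_reversal():
    scores = [1, 2, 3, 10, 11, 12]
    labels = ["n"] * 3 + ["p"] * 3
    assert roc_auc(scores, labels, "p").auc == pytest.approx(1.0)
    assert roc_auc(scores, labels, "n").auc == pytest.approx(0.0)
    assert roc_auc(scores, labels, "n", auto_orient=True).auc == 1.0


def test_roc_matches_sklearn_with_ties():
    rng = np.random.default_rng(3)
    for _ in range(20):
        scores = rng.integers(0, 8, 40).astype(float)  # heavy ties
        labels = rng.choice(["n", "p"], 40)
        if len(set(labels)) < 2:
            continue
        ours = roc_auc(scores, labels, "p").auc
        ref = roc_auc_score((labels == "p").astype(int), scores)
        assert ours == pytest.approx(ref)


def test_roc_equals_u_statistic_identity():
    rng = np.random.default_rng(9)
    for _ in range(100):
        n1, n2 = rng.integers(5, 30, 2)
        a = rng.normal(size=n1)
        b = rng.normal(size=n2)
        u = sps.mannwhitneyu(a, b, alternative="two-sided").statistic
        scores = np.concatenate([a, b])
        labels = np.array(["p"] * n1 + ["n"] * n2)
        assert roc_auc(scores, labels, "p").auc == pytest.approx(u / (n1 * n2))


def test_roc_null_centred():
    rng = np.random.default_rng(4)
    scores = rng.normal(size=2000)
    labels = np.array(["p", "n"] * 1000)
    assert 0.45 <= roc_auc(scores, labels, "p").auc <= 0.55


def test_bonferroni():
    assert bonferroni_adjust([0.01, 0.2], m=3) == [pytest.approx(0.03),
                                                   pytest.approx(0.6)]
    assert bonferroni_adjust([1.0]) == [1.0]
    with pytest.raises(ValueError):
        bonferroni_adjust([0.5], m=0)
    with pytest.raises(ValueError):
        bonferroni_adjust([0.0])


@settings(derandomize=True, max_examples=30)
@given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=8))
def test_bonferroni_never_below_raw(ps):
    adj = bonferroni_adjust(ps)
    assert all(a >= p for a, p in zip(adj, ps))
    assert all(a <= 1.0 for a in adj)


def test_rank_ancova_detects_group_shift_given_uncorrelated_covariate():
    """Planted 1-SD shift, covariate pure noise: omnibus p < 0.01 per seed."""
    for seed in range(20):
        rng = np.random.default_rng(seed)
        vals = np.concatenate([rng.normal(0, 1, 30), rng.normal(1, 1, 30),
                               rng.normal(0, 1, 30)])
        grp = np.repeat(["PD", "AP", "control"], 30)
        cov = rng.normal(60, 10, 90)
        res = rank_ancova(vals, grp, cov)
        assert res.p_omnibus < 0.01


def test_rank_ancova_pairwise_structure():
    rng = np.random.default_rng(0)
    vals = rng.normal(size=60)
    grp = np.repeat(["a", "b", "c"], 20)
    cov = rng.normal(size=60)
    res = rank_ancova(vals, grp, cov)
    assert len(res.pairwise) == 3  # k(k-1)/2
    for pw in res.pairwise:
        assert pw.p_adjusted == pytest.approx(min(1.0, 3 * pw.p_raw))
    assert res.df == (2, 57)


def test_rank_ancova_constant_values_degenerate():
    res = rank_ancova([1.0] * 30, np.repeat(["a", "b", "c"], 10),
                      np.arange(30))
    assert res.degenerate and res.p_omnibus == 1.0


def test_rank_ancova_adjusts_out_pure_covariate_effect():
    """Values monotone in covariate, groups only differ in covariate: the
    adjusted test must not reject wildly (naive Kruskal-Wallis does)."""
    rejections_anc = 0
    rejections_kw = 0
    for seed in range(50):
        rng = np.random.default_rng(1000 + seed)
        n = 25
        cov = np.concatenate([rng.normal(52, 6, n), rng.normal(60, 6, n),
                              rng.normal(68, 6, n)])
        vals = 0.1 * cov + rng.normal(0, 1, 3 * n)
        grp = np.repeat(["a", "b", "c"], n)
        rejections_anc += rank_ancova(vals, grp, cov).p_omnibus < 0.05
        rejections_kw += sps.kruskal(vals[:n], vals[n:2 * n],
                                     vals[2 * n:])[1] < 0.05
    assert rejections_anc / 50 <= 0.15
    assert rejections_kw / 50 > 0.3


def test_tests_invariant_under_sample_reordering():
    rng = np.random.default_rng(2)
    vals = rng.normal(size=45)
    grp = np.repeat(["a", "b", "c"], 15)
    cov = rng.normal(size=45)
    perm = rng.permutation(45)
    r1 = rank_ancova(vals, grp, cov)
    r2 = rank_ancova(vals[perm], grp[perm], cov[perm])
    assert r1.p_omnibus == pytest.approx(r2.p_omnibus)
    o1, _ = kruskal_dunn(vals, grp)
    o2, _ = kruskal_dunn(vals[perm], grp[perm])
    assert o1.p_raw == pytest.approx(o2.p_raw)
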