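"""Inference layer: exact small-sample oracles, adjustment, resampling."""

import numpy as np
import pytest
from scipy import stats as sps

from opariant import (correlation_with_slope, kruskal_wallis,
                      median_resampling_ci, pairwise_wilcoxon, rank_sum_test,
                      significance_stars, two_group_permutation_test)


def test_kruskal_wallis_hand_rank_oracle():
    """Three tie-free groups {1,2,3},{4,5,6},{7,8,9}: mean ranks 2, 5, 8
    give H = 12/(9*10) * 3*((2-5)^2 + 0 + (8-5)^2) = 7.2."""
    res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    assert res["H"] == pytest.approx(7.2)
    assert res["p"] == pytest.approx(sps.chi2.sf(7.2, df=2))
    assert res["df"] == 2


def test_kruskal_wallis_identical_groups_has_zero_h():
    res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
    assert res["H"] == pytest.approx(0.0, abs=1e-12)


def test_kruskal_wallis_two_groups_matches_ranksum_chi_square():
    """For k=2 without ties, H equals the squared rank-sum z, so the
    chi-square p equals the two-sided normal p (no continuity correction)."""
    a, b = [1.0, 4.0, 6.0, 9.0], [2.0, 3.0, 7.0, 11.0, 13.0]
    res = kruskal_wallis([a, b])
    na, nb = len(a), len(b)
    ranks = sps.rankdata(np.concatenate([a, b]))
    w = ranks[:na].sum()
    z = (w - na * (na + nb + 1) / 2) / np.sqrt(
        na * nb * (na + nb + 1) / 12)
    assert res["H"] == pytest.approx(z ** 2, rel=1e-10)
    assert res["p"] == pytest.approx(2 * sps.norm.sf(abs(z)), rel=1e-10)


def test_kruskal_wallis_exact_small_sample_matches_ranksum_enumeration():
    """With two tie-free groups the exact KW permutation p equals the exact
    two-sided rank-sum p: 1/3 for {1,2} vs {3,4}."""
    res = kruskal_wallis([[1, 2], [3, 4]])
    assert res["p_exact"] == pytest.approx(1 / 3)


def test_rank_sum_exact_two_sided_enumeration():
    """{1,2} vs {3,4}: the observed split is one of the two most extreme of
    the C(4,2)=6 equally likely rank assignments -> p = 2/6 = 1/3."""
    _, p = rank_sum_test([1, 2], [3, 4])
    assert p == pytest.approx(1 / 3)


def test_rank_sum_identical_groups_p_one():
    _, p = rank_sum_test([1, 2, 3], [1, 2, 3])
    assert p == pytest.approx(1.0)


def test_rank_sum_invariant_under_monotone_transform():
    rng = np.random.default_rng(2)
    a = rng.normal(size=12)
    b = rng.normal(0.8, size=15)
    _, p_raw = rank_sum_test(a, b)
    _, p_exp = rank_sum_test(np.exp(a), np.exp(b))
    _, p_cub = rank_sum_test(a ** 3, b ** 3)
    assert p_raw == pytest.approx(p_exp)
    assert p_raw == pytest.approx(p_cub)


def test_pairwise_wilcoxon_holm_monotone():
    rng = np.random.default_rng(5)
    groups = [rng.normal(loc, size=12) for loc in (0.0, 0.5, 1.5)]
    comparisons = pairwise_wilcoxon(groups, labels=["a", "b", "c"], seed=0,
                                    n_resamples=500)
    assert len(comparisons) == 3
    raws = [c.p_raw for c in comparisons]
    adjs = [c.p_adjusted for c in comparisons]
    assert all(adj >= raw - 1e-15 for raw, adj in zip(raws, adjs))
    # Holm never reorders the significance ranking
    assert np.array_equal(np.argsort(raws), np.argsort(adjs))
    for c in comparisons:
        lo_a, hi_a = c.cis[0]
        assert lo_a <= c.medians[0] <= hi_a


def test_permutation_test_identical_multisets():
    assert two_group_permutation_test([1, 2, 3], [1, 2, 3]) == \
        pytest.approx(1.0)


def test_permutation_test_exact_enumeration_oracle():
    """{1,2,3} vs {101,102,103}: of the 20 label splits, the observed one,
    its mirror, and the {1,2,101}/{3,102,103} pair all attain
    |median difference| = 100 (3-element medians are middle values), so the
    exact two-sided p is 4/20."""
    p = two_group_permutation_test([1, 2, 3], [101, 102, 103])
    assert p == pytest.approx(4 / 20)
    # brute-force enumeration oracle
    from itertools import combinations
    pooled = np.array([1, 2, 3, 101, 102, 103], dtype=float)
    hits = 0
    for chosen in combinations(range(6), 3):
        mask = np.zeros(6, dtype=bool)
        mask[list(chosen)] = True
        if abs(np.median(pooled[mask]) - np.median(pooled[~mask])) >= 100:
            hits += 1
    assert p == pytest.approx(hits / 20)


def test_permutation_monte_carlo_converges_to_exact():
    rng = np.random.default_rng(7)
    a = rng.normal(size=6)
    b = rng.normal(1.0, size=6)
    p_exact = two_group_permutation_test(a, b)  # n=12 -> enumeration
    p_mc = two_group_permutation_test(a, b, n_perm=20000, seed=1,
                                      exact_max_n=0)
    se = np.sqrt(p_exact * (1 - p_exact) / 20000)
    assert abs(p_mc - p_exact) < 3 * se + 1 / 20000


def test_median_ci_degenerate_sample():
    assert median_resampling_ci([5, 5, 5, 5], seed=0) == (5.0, 5.0, 5.0)


def test_median_ci_deterministic_given_seed():
    rng = np.random.default_rng(9)
    x = rng.normal(size=50)
    assert median_resampling_ci(x, seed=4) == median_resampling_ci(x, seed=4)
    lo, med, hi = median_resampling_ci(x, seed=4)
    assert lo <= med <= hi


def test_median_ci_width_shrinks_with_sample_size():
    rng = np.random.default_rng(10)
    widths = {}
    for n in (50, 200):
        ws = []
        for rep in range(20):
            x = rng.normal(size=n)
            lo, _, hi = median_resampling_ci(x, n_resamples=2000, seed=rep)
            ws.append(hi - lo)
        widths[n] = np.median(ws)
    assert widths[200] < widths[50]


def test_median_ci_warns_on_tiny_resample_count():
    with pytest.warns(UserWarning):
        median_resampling_ci([1.0, 2.0, 3.0], n_resamples=50, seed=0)


def test_correlation_affine_cases():
    x = np.arange(10.0)
    res = correlation_with_slope(x, x)
    assert res.r == pytest.approx(1.0)
    assert res.slope == pytest.approx(1.0)
    res = correlation_with_slope(x, -2 * x + 3)
    assert res.r == pytest.approx(-1.0)
    assert res.slope == pytest.approx(-2.0)
    assert res.intercept == pytest.approx(3.0)


def test_correlation_rejects_degenerate_input():
    with pytest.raises(ValueError):
        correlation_with_slope([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        correlation_with_slope([1.0, 2.0], [1.0, 2.0])


def test_significance_tiers():
    assert significance_stars(0.2) == "n.s."
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.004) == "**"
    assert significance_stars(5e-4) == "***"
    assert significance_stars(5e-5) == "****"


def test_empty_group_rejected():
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 2], []])
    with pytest.raises(ValueError):
        two_group_permutation_test([], [1.0])
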