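"""Exact nonparametric tests against independent enumeration oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from cowjbt.nonparam import (
    bonferroni_adjust,
    fisher_freeman_halton,
    friedman_block,
    spearman_safe,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)


# -- independent brute-force oracles (itertools, no dynamic programming) ----


def oracle_signed_rank_p(diffs):
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    v_obs = ranks[d > 0].sum()
    vs = np.array(
        [
            np.sum(ranks[np.array(s, dtype=bool)])
            for s in itertools.product([False, True], repeat=len(d))
        ]
    )
    lo = np.mean(vs <= v_obs + 1e-9)
    hi = np.mean(vs >= v_obs - 1e-9)
    return min(1.0, 2.0 * min(lo, hi))


def oracle_rank_sum_p(a, b):
    na = len(a)
    ranks = stats.rankdata(np.concatenate([a, b]))
    obs = ranks[:na].sum()
    sums = np.array(
        [np.sum(ranks[list(idx)]) for idx in itertools.combinations(range(len(ranks)), na)]
    )
    lo = np.mean(sums <= obs + 1e-9)
    hi = np.mean(sums >= obs - 1e-9)
    return min(1.0, 2.0 * min(lo, hi))


class TestWilcoxonSignedRank:
    def test_nine_pairs_all_one_sign_reproduces_small_sample_p(self):
        res = wilcoxon_signed_rank([-1, -2, -3, -4, -5, -6, -7, -8, -9])
        assert res.statistic == 0.0  # V = 0
        assert res.p_value == pytest.approx(2 / 2**9)
        assert round(res.p_value, 3) == 0.004

    def test_three_positive_differences(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert res.statistic == 6.0
        assert res.p_value == pytest.approx(0.25)

    def test_all_zero_differences_undefined(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert not res.defined
        assert "zero" in res.note

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(60):
            n = rng.integers(2, 9)
            d = np.round(rng.normal(0, 2, n), 1)  # rounding induces ties/zeros
            if np.all(d == 0):
                continue
            res = wilcoxon_signed_rank(d)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(oracle_signed_rank_p(d), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(30):
            d = rng.normal(0, 1, int(rng.integers(4, 13)))
            res = wilcoxon_signed_rank(d)
            ref = stats.wilcoxon(d, mode="exact", alternative="two-sided")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_sample_normal_approximation(self, rng):
        d = rng.normal(0.3, 1, 40)
        res = wilcoxon_signed_rank(d)
        assert res.method == "approximate"
        ref = stats.wilcoxon(d, mode="approx", alternative="two-sided", correction=False)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_type_one_error_near_nominal_level(self, rng):
        # exact null distribution of V for continuous data, n = 10
        n, reps, rejections = 10, 10_000, 0
        for _ in range(reps):
            d = rng.normal(0, 1, n)
            if wilcoxon_signed_rank(d).p_value <= 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07


class TestWilcoxonRankSum:
    def test_two_versus_two(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.p_value == pytest.approx(1 / 3)
        assert res.statistic == 0.0  # Mann-Whitney U of the first group

    def test_identical_multisets_give_p_one(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_singleton_against_ten(self):
        res = wilcoxon_rank_sum([1], list(range(2, 12)))
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 11)

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(60):
            na, nb = rng.integers(2, 6, 2)
            a = np.round(rng.normal(0, 2, na), 1)
            b = np.round(rng.normal(0.5, 2, nb), 1)
            res = wilcoxon_rank_sum(a, b)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(oracle_rank_sum_p(a, b), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(30):
            a = rng.normal(0, 1, int(rng.integers(3, 8)))
            b = rng.normal(0, 1, int(rng.integers(3, 8)))
            res = wilcoxon_rank_sum(a, b)
            ref = stats.mannwhitneyu(a, b, method="exact", alternative="two-sided")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_rejects_empty_group(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_type_one_error_near_nominal_level(self, rng):
        reps, rejections = 10_000, 0
        for _ in range(reps):
            a = rng.normal(0, 1, 9)
            b = rng.normal(0, 1, 6)
            if wilcoxon_rank_sum(a, b).p_value <= 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07


class TestFreemanHalton:
    def test_published_trained_proportions_table(self):
        res = fisher_freeman_halton([[7, 5], [9, 3], [10, 2]])
        assert res.p_value == pytest.approx(0.526, abs=1e-3)

    def test_no_association_two_identical_rows(self):
        assert fisher_freeman_halton([[5, 3], [5, 3]]).p_value == pytest.approx(1.0)

    def test_diagonal_two_by_two(self):
        assert fisher_freeman_halton([[1, 0], [0, 1]]).p_value == pytest.approx(1.0)

    def test_reduces_to_classical_fisher_on_2x2(self, rng):
        for _ in range(40):
            t = rng.integers(0, 8, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            res = fisher_freeman_halton(t)
            _, ref = stats.fisher_exact(t)
            assert res.p_value == pytest.approx(ref, abs=1e-9)

    def test_degenerate_margin_gives_p_one(self):
        assert fisher_freeman_halton([[4, 0], [3, 0], [5, 0]]).p_value == 1.0

    def test_rejects_non_integer_counts(self):
        with pytest.raises(ValueError):
            fisher_freeman_halton([[1.5, 2], [3, 4]])


class TestFriedman:
    def test_perfect_concordance_three_blocks(self):
        values = [1, 2, 3] * 3
        treatment = ["a", "b", "c"] * 3
        block = ["b1"] * 3 + ["b2"] * 3 + ["b3"] * 3
        res = friedman_block(values, treatment, block)
        assert res.statistic == pytest.approx(6.0)

    def test_all_tied_blocks_give_null_result(self):
        values = [5, 5, 5] * 3
        treatment = ["a", "b", "c"] * 3
        block = ["b1"] * 3 + ["b2"] * 3 + ["b3"] * 3
        res = friedman_block(values, treatment, block)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_incomplete_blocks_dropped_with_warning(self):
        values = [1, 2, 3, 1, 2, 3, 9]
        treatment = ["a", "b", "c", "a", "b", "c", "a"]
        block = ["b1"] * 3 + ["b2"] * 3 + ["b3"]
        with pytest.warns(UserWarning, match="incomplete block"):
            res = friedman_block(values, treatment, block)
        assert res.n_effective == 2

    def test_matches_scipy_on_random_complete_blocks(self, rng):
        k, n = 3, 8
        data = rng.normal(0, 1, size=(n, k))
        values = data.ravel()
        treatment = list("abc") * n
        block = np.repeat([f"b{i}" for i in range(n)], k)
        res = friedman_block(values, treatment, block)
        chi2, p = stats.friedmanchisquare(*data.T)
        assert res.statistic == pytest.approx(chi2)
        assert res.p_value == pytest.approx(p)


class TestSpearmanSafe:
    def test_identical_ranks(self):
        res = spearman_safe([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.statistic == pytest.approx(1.0)

    def test_reversed_ranks(self):
        res = spearman_safe([1, 2, 3], [3, 2, 1])
        assert res.statistic == pytest.approx(-1.0)

    def test_null_variance_is_flagged_not_numeric(self):
        res = spearman_safe([1, 2, 3], [7, 7, 7])
        assert not res.defined
        assert res.note == "null variance"

    def test_rho_matches_scipy(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 12))
            x = np.round(rng.normal(0, 1, n), 1)
            y = np.round(rng.normal(0, 1, n), 1)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = spearman_safe(x, y)
            ref = stats.spearmanr(x, y)
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)

    def test_exact_permutation_p_matches_enumeration_oracle(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.5, 8.5])
        res = spearman_safe(x, y)
        assert res.method == "exact"
        # independent oracle: Pearson correlation of ranks over all 6!
        # pairings of the y-ranks against the fixed x-ranks
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        obs = np.corrcoef(rx, ry)[0, 1]
        rhos = np.array(
            [np.corrcoef(rx, ry[list(p)])[0, 1] for p in itertools.permutations(range(6))]
        )
        oracle = np.mean(np.abs(rhos) >= abs(obs) - 1e-12)
        assert res.p_value == pytest.approx(oracle, abs=1e-9)

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            spearman_safe([1, 2, 3], [1, 2])


class TestBonferroni:
    @pytest.mark.parametrize("p, m, expected", [(0.4, 3, 1.0), (0.01, 3, 0.03), (0.0, 7, 0.0)])
    def test_adjustment(self, p, m, expected):
        assert bonferroni_adjust(p, m) == pytest.approx(expected)

    def test_vectorised(self):
        out = bonferroni_adjust([0.01, 0.4], 3)
        assert out == pytest.approx([0.03, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.2], 2)
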