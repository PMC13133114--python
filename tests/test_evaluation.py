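"""Evaluation metrics: intervals, exact tests, agreement, ranking."""

import math

import numpy as np
import pandas as pd
import pytest

import featsieve as fs
from featsieve.evaluate import score_comparison


class TestWilsonCI:
    @pytest.mark.parametrize(
        "k,n,lo,hi",
        [(58, 274, 17, 26), (0, 10, 0, 28), (19, 91, 14, 30), (18, 320, 4, 9)],
    )
    def test_reproduces_published_interval_brackets(self, k, n, lo, hi):
        a, b = fs.wilson_ci(k, n)
        assert (round(100 * a), round(100 * b)) == (lo, hi)

    def test_lower_bound_exactly_zero_at_zero_successes(self):
        for n in (1, 10, 1000):
            assert fs.wilson_ci(0, n)[0] == 0.0

    @pytest.mark.parametrize("k,n", [(0, 5), (3, 7), (50, 50), (250, 1000)])
    def test_interval_contains_point_estimate(self, k, n):
        lo, hi = fs.wilson_ci(k, n)
        assert lo <= k / n <= hi

    def test_width_shrinks_with_sample_size(self):
        w = lambda k, n: np.subtract(*fs.wilson_ci(k, n)[::-1])
        assert w(200, 1000) < w(20, 100) < w(2, 10)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            fs.wilson_ci(0, 0)


def two_sided_fisher_oracle(a, b, c, d):
    """Enumeration oracle: sum point probabilities <= observed (fixed margins)."""
    r1, c1, n = a + b, a + c, a + b + c + d

    def point(x):
        return (
            math.comb(r1, x) * math.comb(n - r1, c1 - x) / math.comb(n, c1)
        )

    p_obs = point(a)
    return sum(
        point(x)
        for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
        if point(x) <= p_obs * (1 + 1e-9)
    )


class TestFisherTwoSided:
    def test_reproduces_published_aggregate_comparison(self):
        assert fs.fisher_two_sided([[14, 31], [1, 44]]) == pytest.approx(3e-4, abs=1e-4)

    def test_identical_rows_give_unity(self):
        assert fs.fisher_two_sided([[5, 5], [5, 5]]) == 1.0

    def test_empty_margin_warns_and_returns_one(self):
        assert fs.fisher_two_sided([[0, 0], [3, 4]]) == 1.0

    @pytest.mark.parametrize(
        "table", [(3, 5, 7, 2), (0, 10, 10, 0), (4, 4, 4, 4), (1, 9, 2, 15), (14, 6, 3, 17)]
    )
    def test_matches_enumeration_oracle_on_small_tables(self, table):
        a, b, c, d = table
        assert fs.fisher_two_sided([[a, b], [c, d]]) == pytest.approx(
            two_sided_fisher_oracle(a, b, c, d), rel=1e-9
        )

    @pytest.mark.parametrize("table", [(3, 5, 7, 2), (1, 9, 2, 15)])
    def test_invariant_under_simultaneous_row_and_column_swap(self, table):
        a, b, c, d = table
        assert fs.fisher_two_sided([[a, b], [c, d]]) == pytest.approx(
            fs.fisher_two_sided([[d, c], [b, a]])
        )


class TestCohensKappa:
    def test_identical_raters_give_unity(self):
        r = [1, 2, 3, 4, 1, 2]
        assert fs.cohens_kappa(r, r) == 1.0

    def test_hand_computed_two_category_example(self):
        # po = 0.8, pe = 0.5 -> kappa = 0.6
        r1 = [1, 1, 1, 1, 1, 2, 2, 2, 2, 2]
        r2 = [1, 1, 1, 1, 2, 2, 2, 2, 2, 1]
        assert fs.cohens_kappa(r1, r2) == pytest.approx(0.6)

    def test_independent_raters_give_near_zero(self, rng):
        n = 10_000
        r1 = rng.integers(1, 5, n)
        r2 = rng.integers(1, 5, n)
        # po ~ 0.25, pe = 0.25: 3 SE of chance agreement
        se = math.sqrt(0.25 * 0.75 / n) / 0.75
        assert abs(fs.cohens_kappa(r1, r2)) < 3 * se

    def test_constant_equal_raters_defined_as_unity(self):
        assert fs.cohens_kappa([2, 2, 2], [2, 2, 2]) == 1.0


class TestBinarizedAgreement:
    def test_identical_and_complementary_flags(self):
        f = [True, False, True]
        assert fs.binarized_agreement(f, f) == 1.0
        assert fs.binarized_agreement(f, [not x for x in f]) == 0.0

    def test_partial_agreement_fraction(self):
        a = [True] * 10
        b = [True] * 7 + [False] * 3
        assert fs.binarized_agreement(a, b) == pytest.approx(0.7)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fs.binarized_agreement([], [])


class TestInjectDistractors:
    real = [f"r{i}" for i in range(30)]
    pool = [f"p{i}" for i in range(40)]

    def test_ceil_rule_adds_six_distractors_to_thirty(self):
        combined, labels = fs.inject_distractors(self.real, self.pool, 0.2, seed=1)
        assert len(combined) == 36
        assert sum(labels.values()) == 6

    def test_zero_fraction_is_identity(self):
        combined, labels = fs.inject_distractors(self.real, self.pool, 0.0, seed=1)
        assert combined == self.real and not any(labels.values())

    def test_deterministic_under_seed(self):
        a, _ = fs.inject_distractors(self.real, self.pool, 0.2, seed=9)
        b, _ = fs.inject_distractors(self.real, self.pool, 0.2, seed=9)
        assert a == b

    def test_no_duplicate_candidate_ids(self):
        combined, _ = fs.inject_distractors(self.real, self.pool, 0.5, seed=2)
        assert len(set(combined)) == len(combined)

    def test_insufficient_pool_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            fs.inject_distractors(self.real, ["p0"], 0.2, seed=1)


class TestWelchTTest:
    def test_identical_groups_give_unity(self):
        a = [2.0, 3.0, 2.5, 3.5]
        assert fs.welch_ttest(a, a) == 1.0

    def test_far_separated_groups_overwhelmingly_significant(self, rng):
        a = rng.normal(1.0, 0.1, 20)
        b = rng.normal(4.0, 0.1, 20)
        assert fs.welch_ttest(a, b) < 1e-10

    def test_null_rejection_rate_near_alpha(self, rng):
        n_rep, n = 10_000, 12
        a = rng.normal(size=(n_rep, n))
        b = rng.normal(size=(n_rep, n))
        from scipy import stats

        # vectorized reference run of the same test statistic
        pvals = stats.ttest_ind(a, b, axis=1, equal_var=False)[1]
        # spot-check our scalar wrapper against the vectorized path
        for i in range(0, n_rep, 2500):
            assert fs.welch_ttest(a[i], b[i]) == pytest.approx(pvals[i])
        rate = (pvals < 0.05).mean()
        assert 0.04 <= rate <= 0.06

    def test_degenerate_variance_cases(self):
        assert fs.welch_ttest([1.0, 1.0], [1.0, 1.0]) == 1.0
        assert fs.welch_ttest([1.0, 1.0], [2.0, 2.0]) == 0.0


class TestRankingMetrics:
    def test_ideally_sorted_list_gives_unity(self):
        assert fs.ndcg([4, 3, 3, 2, 1]) == 1.0

    def test_single_item_gives_unity(self):
        assert fs.ndcg([2]) == 1.0

    def test_hand_computed_two_item_inversion(self):
        dcg = 1 + 4 / math.log2(3)
        idcg = 4 + 1 / math.log2(3)
        assert fs.ndcg([1, 4]) == pytest.approx(dcg / idcg)
        assert fs.ndcg([1, 4]) == pytest.approx(0.7608, abs=5e-4)

    def test_all_zero_relevance_defined_as_zero(self):
        assert fs.ndcg([0, 0, 0]) == 0.0

    def test_permutation_invariant_denominator(self, rng):
        rel = rng.integers(1, 5, 10)
        perm = rng.permutation(rel)
        # same multiset of relevances -> same ideal DCG; NDCG=1 iff sorted
        assert fs.ndcg(np.sort(rel)[::-1]) == 1.0
        assert fs.ndcg(perm) <= 1.0

    @pytest.mark.parametrize("ranked,expected", [
        ([4, 1, 1], 1.0),
        ([1, 2, 3, 1], 1 / 3),
        ([2, 2, 2, 4], 1 / 4),
    ])
    def test_mrr_reciprocal_rank_of_first_relevant(self, ranked, expected):
        assert fs.mrr(ranked, threshold=3) == pytest.approx(expected)

    def test_mrr_boolean_flags_and_no_relevant_item(self):
        assert fs.mrr([False, True, False]) == 0.5
        assert fs.mrr([1, 1, 2], threshold=3) == 0.0


def test_score_comparison_separates_real_from_distractors(rng):
    n = 40
    records = pd.DataFrame(
        {
            "novelty": rng.integers(1, 5, 2 * n),
            "plausibility": np.r_[rng.integers(3, 5, n), rng.integers(1, 3, n)],
            "utility": np.r_[rng.integers(2, 5, n), rng.integers(1, 3, n)],
            "interestingness": np.r_[rng.integers(2, 5, n), rng.integers(1, 4, n)],
            "is_distractor": np.r_[np.zeros(n, bool), np.ones(n, bool)],
        }
    )
    out = score_comparison(records).set_index("dimension")
    assert out.loc["plausibility", "mean_real"] > out.loc["plausibility", "mean_distractor"]
    assert out.loc["plausibility", "pvalue"] < 0.01
    assert set(out.index) == {"novelty", "plausibility", "utility", "interestingness"}
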