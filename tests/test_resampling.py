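"""Unit and property tests for the statistical kernel."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tadcomp.genome_domains import GenomicInterval
from tadcomp.resampling import (
    fisher_exact_2x2,
    interval_overlap_count,
    label_permutation_test,
    mann_whitney_u,
    shuffle_intervals,
    shuffle_overlap_test,
)


def enumerate_mw_p(x, y, alternative="two-sided"):
    """Exact Mann-Whitney p by enumerating all rank assignments."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    n = len(pooled)
    u_obs = sum(1 for xi in x for yi in y if xi > yi)
    u_null = []
    for combo in itertools.combinations(range(n), len(x)):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(n) if i not in combo]
        u_null.append(sum(1 for xi in xs for yi in ys if xi > yi))
    u_null = np.array(u_null)
    p_greater = np.mean(u_null >= u_obs)
    p_less = np.mean(u_null <= u_obs)
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2.0 * min(p_greater, p_less))


def enumerate_fisher_p(a, b, c, d):
    """Two-sided Fisher p via exact rational hypergeometric enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(k):
        return (
            Fraction(math.comb(col1, k))
            * Fraction(math.comb(n - col1, row1 - k))
            / Fraction(math.comb(n, row1))
        )

    p_obs = prob(a)
    total = Fraction(0)
    for k in range(max(0, row1 - (n - col1)), min(row1, col1) + 1):
        pk = prob(k)
        if pk <= p_obs:
            total += pk
    return float(total)


class TestMannWhitney:
    def test_small_sample_exact_p(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets_give_p_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_exact_and_asymptotic_agree_at_moderate_n(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 15)
        y = rng.normal(0.3, 1, 15)
        _, p_exact = mann_whitney_u(x, y)  # 225 <= 400 -> exact route
        p_asym = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
        assert abs(p_exact - p_asym) < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @given(
        st.lists(st.integers(0, 1000), min_size=2, max_size=6, unique=True),
        st.lists(st.integers(1001, 2000), min_size=2, max_size=6, unique=True),
        st.sampled_from(["exp", "cube", "affine"]),
    )
    def test_invariant_under_monotone_transform(self, x, y, transform):
        """Rank-based: any strictly monotone transform leaves p unchanged."""
        f = {
            "exp": lambda v: math.exp(v / 500),
            "cube": lambda v: v**3,
            "affine": lambda v: 2.5 * v + 7,
        }[transform]
        _, p1 = mann_whitney_u(x, y)
        _, p2 = mann_whitney_u([f(v) for v in x], [f(v) for v in y])
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            (((3, 1), (1, 3)), 0.485714285714),
            (((5, 0), (0, 5)), 2 / math.comb(10, 5)),
            (((2, 2), (2, 2)), 1.0),
        ],
    )
    def test_known_tables(self, table, expected):
        _, p = fisher_exact_2x2(table)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_zero_margin(self):
        odds, p = fisher_exact_2x2(((0, 0), (5, 5)))
        assert math.isnan(odds)
        assert p == 1.0

    def test_balanced_table_odds_ratio_one(self):
        odds, _ = fisher_exact_2x2(((10, 20), (5, 10)))
        assert odds == pytest.approx(1.0)

    def test_one_sided_tails_sum_over_two_sided(self):
        _, p_g = fisher_exact_2x2(((8, 2), (3, 7)), alternative="greater")
        _, p_l = fisher_exact_2x2(((8, 2), (3, 7)), alternative="less")
        # tails overlap only in the observed table
        assert p_g + p_l >= 1.0


class TestShuffleIntervals:
    def test_full_length_interval_forced_to_origin(self):
        iv = GenomicInterval("X", 10, 110)
        rng = np.random.default_rng(0)
        out = shuffle_intervals([iv], 100, rng)
        assert out[0].start == 0 and out[0].end == 100

    def test_lengths_conserved(self):
        rng = np.random.default_rng(1)
        ivs = [GenomicInterval("X", s, s + ln) for s, ln in [(0, 10), (50, 25), (200, 5)]]
        out = shuffle_intervals(ivs, 1000, rng)
        assert sorted(len(iv) for iv in out) == sorted(len(iv) for iv in ivs)

    def test_uniform_placement_mean(self):
        """Length 50 on a 100 bp chromosome: start ~ Uniform{0..50}, mean 25."""
        rng = np.random.default_rng(2)
        starts = [
            shuffle_intervals([GenomicInterval("X", 0, 50)], 100, rng)[0].start
            for _ in range(2000)
        ]
        assert 20 <= np.mean(starts) <= 30

    def test_oversized_interval_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            shuffle_intervals([GenomicInterval("X", 0, 200)], 100, rng)


def brute_force_overlap_count(domains, features):
    return sum(
        1
        for f in features
        if any(d.chrom == f.chrom and d.start < f.end and f.start < d.end
               for d in domains)
    )


class TestOverlapCount:
    def test_feature_counted_once(self):
        domains = [GenomicInterval("X", 10, 20)]
        feats = [GenomicInterval("X", 5, 12), GenomicInterval("X", 30, 40)]
        assert interval_overlap_count(domains, feats) == 1

    def test_half_open_adjacency(self):
        assert (
            interval_overlap_count(
                [GenomicInterval("X", 10, 20)], [GenomicInterval("X", 20, 30)]
            )
            == 0
        )

    def test_random_fixtures_match_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            domains = [
                GenomicInterval("X", int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 900, 20), rng.integers(1, 80, 20))
            ]
            feats = [
                GenomicInterval("X", int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 950, 30), rng.integers(1, 40, 30))
            ]
            assert interval_overlap_count(domains, feats) == brute_force_overlap_count(
                domains, feats
            )


class TestShuffleOverlapTest:
    def test_empty_features(self):
        domains = [GenomicInterval("X", 0, 10)]
        res = shuffle_overlap_test(domains, [], 100, n_shuffles=99, seed=0)
        assert res.observed == 0
        assert (res.null_sample == 0).all()
        assert res.p_depletion == 1.0 and res.p_enrichment == 1.0

    def test_domains_cover_whole_chromosome(self):
        domains = [GenomicInterval("X", 0, 100)]
        feats = [GenomicInterval("X", i, i + 1) for i in range(0, 100, 10)]
        res = shuffle_overlap_test(domains, feats, 100, n_shuffles=99, seed=0)
        assert res.observed == len(feats)
        assert (res.null_sample == len(feats)).all()
        assert res.p_depletion == 1.0 and res.p_enrichment == 1.0

    def test_depleted_features_detected(self):
        # domains confined to the left half; all features on the right half
        domains = [GenomicInterval("X", i, i + 50) for i in range(0, 1000, 100)]
        feats = [GenomicInterval("X", i, i + 2) for i in range(1000, 2000, 20)]
        res = shuffle_overlap_test(domains, feats, 2000, n_shuffles=999, seed=3)
        assert res.observed == 0
        assert res.p_depletion < 0.05
        assert res.expected > 1

    def test_reproducible_from_seed(self):
        domains = [GenomicInterval("X", 100, 200)]
        feats = [GenomicInterval("X", i, i + 5) for i in range(0, 900, 37)]
        r1 = shuffle_overlap_test(domains, feats, 1000, n_shuffles=200, seed=11)
        r2 = shuffle_overlap_test(domains, feats, 1000, n_shuffles=200, seed=11)
        assert (r1.null_sample == r2.null_sample).all()
        assert r1.p_depletion == r2.p_depletion

    def test_non_overlapping_mode_yields_disjoint_draws(self):
        domains = [GenomicInterval("X", 0, 300), GenomicInterval("X", 400, 700)]
        feats = [GenomicInterval("X", i, i + 1) for i in range(0, 1000, 50)]
        res = shuffle_overlap_test(
            domains, feats, 1000, n_shuffles=50, seed=5, allow_overlap=False
        )
        assert res.n_shuffles == 50

    def test_add_one_floor(self):
        domains = [GenomicInterval("X", 0, 500)]
        feats = [GenomicInterval("X", i, i + 1) for i in range(0, 1000, 10)]
        res = shuffle_overlap_test(domains, feats, 1000, n_shuffles=99, seed=0)
        floor = 1 / 100
        assert res.p_depletion >= floor and res.p_enrichment >= floor


class TestLabelPermutation:
    def test_constant_values_give_p_one(self):
        values = np.ones(20)
        labels = ["a"] * 10 + ["b"] * 10
        res = label_permutation_test(values, labels, n_perm=99, seed=0)
        assert res.statistic_observed == 0.0
        assert res.p == 1.0

    def test_statistic_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1, 16)
        labels = np.array(["a"] * 8 + ["b"] * 8)
        swapped = np.where(labels == "a", "b", "a")
        r1 = label_permutation_test(values, labels, n_perm=9, seed=0)
        r2 = label_permutation_test(values, swapped, n_perm=9, seed=0)
        assert r1.statistic_observed == pytest.approx(-r2.statistic_observed)

    def test_sampled_p_approximates_exact_enumeration(self):
        """On 12 values the sampled null converges to the exhaustive one."""
        rng = np.random.default_rng(9)
        values = rng.normal(0, 1, 12)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        obs = np.median(values[:6]) - np.median(values[6:])
        null = []
        for combo in itertools.combinations(range(12), 6):
            rest = [i for i in range(12) if i not in combo]
            null.append(np.median(values[list(combo)]) - np.median(values[rest]))
        null = np.array(null)
        p_exact = min(1.0, 2 * min(np.mean(null >= obs), np.mean(null <= obs)))
        res = label_permutation_test(values, labels, n_perm=4999, seed=1)
        assert res.p == pytest.approx(p_exact, abs=0.03)

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValueError):
            label_permutation_test([1, 2], ["a", "b"], statistic="diff_of_modes")

    def test_separated_groups_small_p(self):
        """Continuously separated groups: almost no shuffle reaches T_obs.

        (With exactly two distinct values a median statistic ties with the
        observed split in a large fraction of shuffles, so the separation
        must be continuous for the median-based p to be small.)
        """
        rng = np.random.default_rng(4)
        values = np.concatenate(
            [rng.normal(10, 0.1, 20), rng.normal(0, 0.1, 20)]
        )
        labels = ["hi"] * 20 + ["lo"] * 20
        res = label_permutation_test(values, labels, n_perm=1999, seed=2, tail="greater")
        assert res.p <= 0.01
        res_means = label_permutation_test(
            np.concatenate([np.full(20, 10.0), np.zeros(20)]),
            labels,
            statistic="diff_of_means",
            n_perm=1999,
            seed=2,
            tail="greater",
        )
        assert res_means.p <= 0.01


class TestOracleAgreement:
    """Spot checks against independent enumeration (deeper sweep lives in
    the acceptance suite)."""

    def test_mw_matches_enumeration(self):
        rng = np.random.default_rng(0)
        x = list(rng.normal(0, 1, 4))
        y = list(rng.normal(0.5, 1, 5))
        for alt in ("two-sided", "greater", "less"):
            _, p = mann_whitney_u(x, y, alternative=alt)
            assert p == pytest.approx(enumerate_mw_p(x, y, alt), abs=1e-12)

    def test_fisher_matches_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b, c, d = (int(v) for v in rng.integers(0, 12, 4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            _, p = fisher_exact_2x2(((a, b), (c, d)))
            assert p == pytest.approx(enumerate_fisher_p(a, b, c, d), abs=1e-10)
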