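"""Cutoff estimators, filtering, ratios, trimming, knockdown responses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tadcomp.expression_metrics import (
    ExpressionTable,
    class_expression_summary,
    class_response_comparison,
    em_background_cutoff,
    filter_expressed,
    knockdown_log2fc,
    match_medians_by_trimming,
    mf_log2_ratio,
    percentile_cutoff,
)


def make_table(values: dict, meta: dict) -> ExpressionTable:
    return ExpressionTable(
        values=pd.DataFrame(values),
        samples=pd.DataFrame(meta).T.rename_axis("sample_id"),
    )


class TestPercentileCutoff:
    def test_interpolated_rank(self):
        est = percentile_cutoff(np.arange(1, 101), 99)
        assert est.cutoff == pytest.approx(99.01)

    def test_constant_input(self):
        assert percentile_cutoff([5.0] * 10, 42).cutoff == 5.0

    def test_midpoint(self):
        assert percentile_cutoff([0.5, 1.0], 50).cutoff == pytest.approx(0.75)

    def test_empty_and_bad_q(self):
        with pytest.raises(ValueError):
            percentile_cutoff([], 99)
        with pytest.raises(ValueError):
            percentile_cutoff([1.0], 100)

    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=40),
        st.floats(1, 99),
    )
    def test_matches_sorted_interpolation_oracle(self, values, q):
        est = percentile_cutoff(values, q)
        v = np.sort(np.asarray(values))
        rank = (len(v) - 1) * q / 100.0
        lo = int(np.floor(rank))
        frac = rank - lo
        expected = v[lo] if lo + 1 >= len(v) else v[lo] * (1 - frac) + v[lo + 1] * frac
        assert est.cutoff == pytest.approx(expected, rel=1e-9, abs=1e-9)


class TestEMCutoff:
    def test_two_constants_recovers_both_levels(self):
        values = np.concatenate([np.zeros(5000), np.full(5000, 10.0)])
        fit, cut = em_background_cutoff(values)
        assert sorted(np.round(fit.means, 6)) == [0.0, 10.0]
        # sigma collapses to the floor: cutoff sits just above 0
        assert 0 < cut.cutoff < 0.1
        assert not fit.converged  # flagged degenerate

    def test_unimodal_data_flagged_degenerate(self):
        rng = np.random.default_rng(3)
        fit, _ = em_background_cutoff(rng.normal(5, 1, 4000))
        assert not fit.converged
        assert fit.detail["degenerate"]

    def test_well_separated_mixture_recovered(self):
        rng = np.random.default_rng(11)
        values = np.concatenate([rng.normal(3, 1, 3000), rng.normal(8, 1, 3000)])
        fit, cut = em_background_cutoff(values)
        assert fit.converged
        assert abs(sorted(fit.means)[0] - 3) < 0.15
        assert abs(sorted(fit.means)[1] - 8) < 0.15
        assert fit.means[fit.background_index] == min(fit.means)
        assert cut.cutoff == pytest.approx(3 + 3.0902, abs=0.25)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            em_background_cutoff(np.arange(10))


class TestFilterExpressed:
    TABLE = make_table(
        {"s1": {"g1": 0.5, "g2": 1.0, "g3": 2.0}, "s2": {"g1": 1.2, "g2": 0.9, "g3": 0.1}},
        {
            "s1": {"sex": "M", "source": "s2", "condition": "control", "platform": "rnaseq"},
            "s2": {"sex": "M", "source": "s2", "condition": "control", "platform": "rnaseq"},
        },
    )

    def test_strictly_greater_than_cutoff(self):
        kept, _ = filter_expressed(self.TABLE, 1.0)
        assert kept == {"g1", "g3"}  # g2 peaks exactly at 1.0 -> excluded

    def test_any_sample_in_scope_suffices(self):
        kept, _ = filter_expressed(self.TABLE, 1.0, scope=["s2"])
        assert kept == {"g1"}

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.exponential(1.0, (20, 3)),
            index=[f"g{i}" for i in range(20)],
            columns=["a", "b", "c"],
        )
        meta = pd.DataFrame(
            {"sex": "M", "source": "s2", "condition": "control", "platform": "rnaseq"},
            index=["a", "b", "c"],
        ).rename_axis("sample_id")
        table = ExpressionTable(values=values, samples=meta)
        kept, _ = filter_expressed(table, 1.0)
        expected = {
            g for g in values.index
            if any(values.loc[g, s] > 1.0 for s in values.columns)
        }
        assert kept == expected


class TestClassSummary:
    def test_five_point_class(self):
        out = class_expression_summary(
            pd.Series({f"g{i}": v for i, v in enumerate([1, 2, 3, 4, 5])}),
            {"c": {f"g{i}" for i in range(5)}},
        )
        row = out.loc["c"]
        assert row["median"] == 3 and row["q1"] == 2 and row["q3"] == 4
        assert row["whisker_low"] == 1 and row["whisker_high"] == 5

    def test_single_gene_class_degenerate(self):
        out = class_expression_summary(pd.Series({"g": 7.0}), {"c": {"g"}})
        row = out.loc["c"]
        assert row["median"] == row["whisker_low"] == row["whisker_high"] == 7.0
        assert row["notch_halfwidth"] == 0.0

    def test_empty_class_reported_missing(self):
        out = class_expression_summary(pd.Series({"g": 1.0}), {"c": set()})
        assert np.isnan(out.loc["c", "median"])
        assert out.loc["c", "n"] == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        vals = pd.Series(rng.normal(0, 1, 200), index=[f"g{i}" for i in range(200)])
        out = class_expression_summary(vals, {"all": set(vals.index)})
        v = np.sort(vals.to_numpy())
        assert out.loc["all", "median"] == pytest.approx(np.median(v))
        q1, q3 = np.percentile(v, [25, 75])
        iqr = q3 - q1
        assert out.loc["all", "whisker_high"] == pytest.approx(v[v <= q3 + 1.5 * iqr].max())
        assert out.loc["all", "notch_halfwidth"] == pytest.approx(
            1.58 * iqr / np.sqrt(200)
        )


class TestMFRatio:
    def build(self, male, female):
        ids = [f"g{i}" for i in range(len(male))]
        return make_table(
            {
                "m1": dict(zip(ids, male)),
                "f1": dict(zip(ids, female)),
            },
            {
                "m1": {"sex": "M", "source": "s2", "condition": "control", "platform": "rnaseq"},
                "f1": {"sex": "F", "source": "kc", "condition": "control", "platform": "rnaseq"},
            },
        )

    def test_equal_expression_gives_zero(self):
        table = self.build([2.0, 4.0], [2.0, 4.0])
        ratios, _ = mf_log2_ratio(table, ["m1"], ["f1"], {"all": {"g0", "g1"}})
        assert (ratios == 0).all()

    def test_half_dose_gives_minus_one(self):
        table = self.build([1.0, 2.0], [2.0, 4.0])
        ratios, per_class = mf_log2_ratio(
            table, ["m1"], ["f1"], {"all": {"g0", "g1"}}
        )
        assert ratios.tolist() == [-1.0, -1.0]
        assert per_class.loc["all", "median_log2_mf"] == -1.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        male = rng.exponential(2, 10)
        female = rng.exponential(2, 10)
        r1, _ = mf_log2_ratio(
            self.build(male, female), ["m1"], ["f1"], {"all": {f"g{i}" for i in range(10)}}
        )
        r2, _ = mf_log2_ratio(
            self.build(2 * male, 2 * female), ["m1"], ["f1"],
            {"all": {f"g{i}" for i in range(10)}},
        )
        assert np.allclose(r1, r2)

    def test_zero_female_mean_dropped(self):
        table = self.build([1.0, 1.0], [0.0, 2.0])
        ratios, per_class = mf_log2_ratio(table, ["m1"], ["f1"], {"all": {"g0", "g1"}})
        assert "g0" not in ratios.index
        assert per_class.loc["all", "n_dropped_zero_female"] == 1


class TestMedianMatching:
    def test_hand_walked_example(self):
        res = match_medians_by_trimming(
            [2.0, 2.0, 2.0], {"a": 1, "b": 2, "c": 3, "d": 4, "e": 5}
        )
        assert res.kept_gene_ids == ["a", "b", "c"]
        assert res.removed_gene_ids == ["e", "d"]
        assert res.target_median == 2.0

    def test_already_below_reference_unchanged(self):
        res = match_medians_by_trimming([10.0], {"a": 1, "b": 2})
        assert res.removed_gene_ids == []
        assert set(res.kept_gene_ids) == {"a", "b"}

    def test_equal_values_above_reference_error(self):
        with pytest.raises(ValueError, match="infeasible"):
            match_medians_by_trimming([1.0], {"a": 5.0, "b": 5.0, "c": 5.0})

    def test_minimality_on_random_fixtures(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            ref = rng.normal(0, 1, 21)
            target = pd.Series(
                rng.normal(0.8, 1, 25), index=[f"g{i}" for i in range(25)]
            )
            try:
                res = match_medians_by_trimming(ref, target)
            except ValueError:
                continue
            assert res.target_median <= res.reference_median
            if res.removed_gene_ids:
                restored = res.kept_gene_ids + [res.removed_gene_ids[-1]]
                assert (
                    np.median(target[restored].to_numpy())
                    > res.reference_median
                )


class TestKnockdownFC:
    def test_no_change_gives_zero(self):
        counts = pd.DataFrame(
            {"c1": [100, 200], "c2": [110, 190]}, index=["g1", "g2"]
        )
        fc = knockdown_log2fc(counts, counts.copy(), platform="rnaseq")
        assert np.allclose(fc, 0)

    def test_halved_cpm_near_minus_one(self):
        # library sizes engineered equal so CPM ratio is the count ratio
        control = pd.DataFrame({"c": [1000, 9000]}, index=["g1", "g2"])
        treatment = pd.DataFrame({"t": [500, 9500]}, index=["g1", "g2"])
        fc = knockdown_log2fc(control, treatment, platform="rnaseq")
        assert fc["g1"] == pytest.approx(-1.0, abs=0.01)

    def test_array_platform_differences(self):
        control = pd.DataFrame({"c1": [5.0, 6.0], "c2": [5.2, 6.2]}, index=["g1", "g2"])
        treatment = pd.DataFrame({"t1": [4.1, 6.1]}, index=["g1", "g2"])
        fc = knockdown_log2fc(control, treatment, platform="array")
        assert fc["g1"] == pytest.approx(4.1 - 5.1)

    def test_random_counts_match_formula(self):
        rng = np.random.default_rng(2)
        ids = [f"g{i}" for i in range(30)]
        control = pd.DataFrame(rng.integers(0, 500, (30, 2)), index=ids, columns=["c1", "c2"])
        treatment = pd.DataFrame(rng.integers(0, 500, (30, 2)), index=ids, columns=["t1", "t2"])
        fc = knockdown_log2fc(control, treatment, platform="rnaseq")
        cpm_c = (control / control.sum()) * 1e6
        cpm_t = (treatment / treatment.sum()) * 1e6
        expected = np.log2(cpm_t.mean(axis=1) + 0.5) - np.log2(cpm_c.mean(axis=1) + 0.5)
        assert np.allclose(fc, expected)

    def test_mismatched_gene_sets_rejected(self):
        control = pd.DataFrame({"c": [1]}, index=["g1"])
        treatment = pd.DataFrame({"t": [1]}, index=["g2"])
        with pytest.raises(ValueError, match="differ"):
            knockdown_log2fc(control, treatment, platform="rnaseq")


class TestClassResponse:
    def test_identical_distributions_large_p(self):
        vals = pd.Series(
            np.tile(np.arange(20, dtype=float), 2),
            index=[f"g{i}" for i in range(40)],
        )
        rep = {f"g{i}" for i in range(20)}
        nonrep = {f"g{i}" for i in range(20, 40)}
        out = class_response_comparison(vals, rep, nonrep)
        assert out["p_two_sided"] > 0.9

    def test_shifted_distribution_detected(self):
        rng = np.random.default_rng(12)
        vals = pd.Series(
            np.concatenate([rng.normal(1, 1, 200), rng.normal(0, 1, 200)]),
            index=[f"g{i}" for i in range(400)],
        )
        rep = {f"g{i}" for i in range(200)}
        nonrep = {f"g{i}" for i in range(200, 400)}
        out = class_response_comparison(vals, rep, nonrep)
        assert out["p_two_sided"] < 0.001
        assert out["median_repressive"] > out["median_non_repressive"]
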