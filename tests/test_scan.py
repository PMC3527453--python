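"""2x2 scoring, Woolf intervals, Wald statistics and the exhaustive scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snpcombo import (
    CombinationScan,
    CountsTable,
    DegenerateTableError,
    bonferroni,
    cohort_from_dataframe,
    odds_ratio_ci,
    two_by_two,
    wald_stat_p,
)
from snpcombo.scan import optimal_or_profile

from conftest import make_subject_frame


class TestTwoByTwo:
    def test_hand_tallied_cells(self, hand_cohort, pair_combination):
        counts = two_by_two(hand_cohort, pair_combination)
        # subject 7 has a missing member genotype -> dropped (complete case)
        assert counts == CountsTable(a=3, b=1, c=1, d=2)

    def test_perfect_separation_cells(self):
        rows = [{"status": 1, "rs9642880": 2} for _ in range(3)]
        rows += [{"status": 0, "rs9642880": 0} for _ in range(3)]
        cohort = cohort_from_dataframe(make_subject_frame(rows))
        from snpcombo import Combination, RiskIndicator

        combo = Combination((RiskIndicator("rs9642880", (1, 2)),))
        counts = two_by_two(cohort, combo)
        assert counts.b == 0 and counts.c == 0

    def test_empty_stratum_errors(self, hand_cohort, pair_combination):
        with pytest.raises(ValueError, match="empty"):
            two_by_two(hand_cohort, pair_combination, stratum="former")

    def test_brute_force_oracle_on_simulated_cohort(self, planted_cohort,
                                                    session_combination):
        counts = two_by_two(planted_cohort, session_combination, "current")
        # independent row-by-row tally over the raw table
        sub = planted_cohort.table[planted_cohort.table["smoking"] == "current"]
        exp = (sub["rs9642880"].isin([1, 2])) & (sub["rs1014971"] == 2)
        ok = (sub["rs9642880"] >= 0) & (sub["rs1014971"] >= 0)
        a = int((exp & ok & (sub["status"] == 1)).sum())
        d = int((~exp & ok & (sub["status"] == 0)).sum())
        assert counts.a == a and counts.d == d


class TestOddsRatio:
    def test_current_smoker_table(self):
        or_, lo, hi = odds_ratio_ci(CountsTable(431, 315, 321, 752))
        assert round(or_, 2) == 3.21
        assert round(lo, 2) == 2.64
        assert round(hi, 2) == 3.90

    def test_symmetric_table_is_null(self):
        or_, lo, hi = odds_ratio_ci(CountsTable(10, 10, 10, 10))
        assert or_ == pytest.approx(1.0)
        assert lo < 1 < hi

    def test_cross_product(self):
        assert odds_ratio_ci(CountsTable(20, 5, 10, 40))[0] == pytest.approx(16.0)

    def test_haldane_correction_on_single_zero_cell(self):
        or_, _, _ = odds_ratio_ci(CountsTable(5, 0, 5, 10))
        assert or_ == pytest.approx((5.5 * 10.5) / (0.5 * 5.5))

    @pytest.mark.parametrize(
        "counts",
        [CountsTable(0, 0, 5, 5), CountsTable(5, 5, 0, 0),
         CountsTable(0, 5, 0, 5), CountsTable(5, 0, 5, 0)],
    )
    def test_empty_margin_is_undefined(self, counts):
        with pytest.raises(DegenerateTableError):
            odds_ratio_ci(counts)


class TestWald:
    def test_null_table_gives_zero(self):
        for t in (CountsTable(10, 10, 10, 10), CountsTable(1, 1, 1, 1)):
            wald, p = wald_stat_p(t)
            assert wald == pytest.approx(0.0)
            assert p == pytest.approx(1.0)

    def test_closed_form_oracle(self):
        a, b, c, d = 431, 315, 321, 752
        expected = np.log((a * d) / (b * c)) ** 2 / (1 / a + 1 / b + 1 / c + 1 / d)
        wald, p = wald_stat_p(CountsTable(a, b, c, d))
        assert wald == pytest.approx(expected, rel=1e-12)

    def test_chi2_tail_equals_squared_z_test(self):
        """chi-square(1) tail at W equals the two-sided normal p at sqrt(W)."""
        for counts in [CountsTable(30, 20, 25, 40), CountsTable(431, 315, 321, 752)]:
            wald, p = wald_stat_p(counts)
            assert p == pytest.approx(2 * stats.norm.sf(np.sqrt(wald)), rel=1e-12)


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected",
                             [(0.5, 3, 1.0), (1e-4, 288, 0.0288), (0.2, 1, 0.2)])
    def test_values(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bonferroni(1.5, 2)
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)


class TestScan:
    def test_all_288_candidates_accounted_for(self, planted_cohort):
        res = CombinationScan(planted_cohort, 2).fit()
        assert res.m == 288
        assert len(res.table) + len(res.excluded) == 288
        assert (res.table["p_adj"] == np.minimum(1, 288 * res.table["p_raw"])).all()

    def test_planted_combination_ranks_first(self, planted_cohort, session_combination):
        res = CombinationScan(planted_cohort, 2).fit()
        assert res.table.iloc[0]["key"] == session_combination.key
        lo, hi = res.table.iloc[0][["ci_lo", "ci_hi"]]
        assert lo < 2.0 < hi  # planted conditional OR

    def test_complement_indicator_or_reciprocal(self, planted_cohort):
        """For k=1 the OR of an indicator and of its complement are exact
        reciprocals whenever no cell is zero."""
        res = CombinationScan(planted_cohort, 1).fit()
        tab = res.table.set_index("key")
        from snpcombo import enumerate_indicators, Combination

        for p in planted_cohort.polymorphisms:
            for ind in enumerate_indicators(p, planted_cohort.domains[p]):
                k1 = Combination((ind,)).key
                k2 = Combination((ind.complement(),)).key
                if k1 in tab.index and k2 in tab.index:
                    row = tab.loc[k1]
                    if min(row["a"], row["b"], row["c"], row["d"]) > 0:
                        assert tab.loc[k1, "odds_ratio"] == pytest.approx(
                            1.0 / tab.loc[k2, "odds_ratio"], rel=1e-12
                        )

    def test_invariant_to_row_and_column_order(self, planted_cohort):
        base = CombinationScan(planted_cohort, 2).fit().table
        shuffled_rows = planted_cohort.table.sample(frac=1, random_state=9)
        reordered_cols = shuffled_rows[
            ["id", "status", "smoking", "age", "gender", "site"]
            + list(planted_cohort.polymorphisms[::-1])
        ]
        cohort2 = cohort_from_dataframe(
            reordered_cols.astype(str), polymorphisms=planted_cohort.polymorphisms
        )
        other = CombinationScan(cohort2, 2).fit().table
        pd.testing.assert_frame_equal(
            base[["key", "a", "b", "c", "d", "odds_ratio", "p_adj"]],
            other[["key", "a", "b", "c", "d", "odds_ratio", "p_adj"]],
        )

    def test_ranking_deterministic_and_metrics_differ(self, planted_cohort):
        by_p = CombinationScan(planted_cohort, 2, metric="p").fit().table
        by_p2 = CombinationScan(planted_cohort, 2, metric="p").fit().table
        pd.testing.assert_frame_equal(by_p, by_p2)
        by_or = CombinationScan(planted_cohort, 2, metric="or").fit().table
        assert (by_or["odds_ratio"].to_numpy() == np.sort(by_or["odds_ratio"])[::-1]).all()

    def test_low_count_results_flagged(self, planted_cohort):
        res = CombinationScan(planted_cohort, 2).fit()
        sparse = res.table[(res.table["a"] < 100) | (res.table["b"] < 100)]
        assert sparse["flagged"].all()
        dense = res.table[(res.table["a"] >= 100) & (res.table["b"] >= 100)]
        assert not dense["flagged"].any()

    def test_summary_mentions_stratum_and_counts(self, planted_cohort):
        text = CombinationScan(planted_cohort, 2, stratum="non").fit().summary(3)
        assert "stratum=non" in text and "candidates=288" in text

    def test_order_out_of_range(self, planted_cohort):
        with pytest.raises(ValueError):
            CombinationScan(planted_cohort, 0)
        with pytest.raises(ValueError):
            CombinationScan(planted_cohort, 8)


def test_optimal_or_profile_shape(planted_cohort):
    prof = optimal_or_profile(planted_cohort, orders=(1, 2), strata=("total", "non"))
    assert len(prof) == 4
    assert set(prof.columns) >= {"stratum", "order", "odds_ratio", "flagged"}
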