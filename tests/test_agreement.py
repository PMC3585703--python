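"""Kappa, diagnostic metrics, chi-square, GA differences and report tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2 as chi2_dist

from gestage.agreement import (
    Comparator,
    ConfusionTable2x2,
    DiscrepancyCategory,
    KappaBand,
    categorize_difference,
    cohen_kappa,
    confusion,
    diagnostic_metrics,
    ga_difference_days,
    ga_distribution_table,
    method_comparison_report,
    preterm_rate,
    rate_chi_square,
    round_half_up,
    stratified_difference_table,
)
from gestage.errors import (
    DegenerateTableError,
    DomainError,
    EmptyComparisonError,
    UndefinedKappaError,
)
from gestage.records import GAEstimate, Method

tables = st.tuples(
    st.integers(0, 60), st.integers(0, 60), st.integers(0, 60), st.integers(0, 60)
)


class TestConfusion:
    def test_identical_lists_have_no_discordance(self):
        t = confusion(["P", "N", "P"], ["P", "N", "P"], "P")
        assert (t.tp, t.fp, t.fn, t.tn) == (2, 0, 0, 1)

    def test_fully_crossed_lists(self):
        t = confusion(["P", "P", "N", "N"], ["N", "N", "P", "P"], "P")
        assert (t.tp, t.fp, t.fn, t.tn) == (0, 2, 2, 0)

    def test_missing_pairs_are_dropped(self):
        t = confusion(["P", None, "N"], ["P", "P", float("nan")], "P")
        assert t.total == 1

    def test_all_missing_raises(self):
        with pytest.raises(EmptyComparisonError):
            confusion([None, None], ["P", "N"], "P")


class TestKappa:
    def test_perfect_agreement(self):
        result = cohen_kappa(ConfusionTable2x2(tp=10, fp=0, fn=0, tn=30))
        assert result.kappa == pytest.approx(1.0)
        assert result.band is KappaBand.ALMOST_PERFECT

    def test_hand_worked_table(self):
        # p_o = 0.85, p_e = 0.50 -> kappa = 0.70
        result = cohen_kappa(ConfusionTable2x2(tp=40, fp=10, fn=5, tn=45))
        assert result.kappa == pytest.approx(0.70)
        assert result.band is KappaBand.SUBSTANTIAL

    def test_independence_proportional_margins_give_zero(self):
        # margins 20/80 vs 30/70: p_o = p_e = 0.62 by construction
        result = cohen_kappa(ConfusionTable2x2(tp=6, fp=14, fn=24, tn=56))
        assert result.kappa == pytest.approx(0.0)
        assert result.band is KappaBand.SLIGHT

    def test_single_cell_marginals_undefined(self):
        with pytest.raises(UndefinedKappaError):
            cohen_kappa(ConfusionTable2x2(tp=25, fp=0, fn=0, tn=0))

    @pytest.mark.parametrize(
        "kappa, band",
        [
            (0.90, KappaBand.ALMOST_PERFECT),
            (0.81, KappaBand.ALMOST_PERFECT),
            (0.76, KappaBand.SUBSTANTIAL),
            (0.55, KappaBand.MODERATE),
            (0.262, KappaBand.FAIR),
            (0.048, KappaBand.SLIGHT),
            (-0.016, KappaBand.POOR),
        ],
    )
    def test_landis_koch_bands(self, kappa, band):
        from gestage.agreement import kappa_band

        assert kappa_band(kappa) is band

    @given(tables)
    @settings(max_examples=300, derandomize=True)
    def test_symmetric_under_transpose(self, cells):
        tp, fp, fn, tn = cells
        t = ConfusionTable2x2(tp=tp, fp=fp, fn=fn, tn=tn)
        if t.total == 0:
            return
        try:
            forward = cohen_kappa(t).kappa
        except UndefinedKappaError:
            with pytest.raises(UndefinedKappaError):
                cohen_kappa(t.transpose())
            return
        assert cohen_kappa(t.transpose()).kappa == pytest.approx(forward)


class TestDiagnosticMetrics:
    def test_perfect_table(self):
        m = diagnostic_metrics(ConfusionTable2x2(tp=12, fp=0, fn=0, tn=30))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (1.0, 1.0, 1.0, 1.0)

    def test_hand_worked_ratios(self):
        m = diagnostic_metrics(ConfusionTable2x2(tp=40, fp=10, fn=5, tn=45))
        assert m.sensitivity == pytest.approx(40 / 45)
        assert m.specificity == pytest.approx(45 / 55)
        assert m.ppv == pytest.approx(0.80)
        assert m.npv == pytest.approx(0.90)

    def test_zero_denominator_marks_not_defined(self):
        m = diagnostic_metrics(ConfusionTable2x2(tp=0, fp=0, fn=5, tn=45))
        assert m.ppv is None
        assert m.sensitivity == 0.0  # zero numerator over positive denominator

    def test_transposing_swaps_sensitivity_and_ppv(self):
        t = ConfusionTable2x2(tp=33, fp=7, fn=12, tn=48)
        assert diagnostic_metrics(t.transpose()).sensitivity == pytest.approx(
            diagnostic_metrics(t).ppv
        )


class TestRateChiSquare:
    def test_identical_counts_give_zero(self):
        chi2, p = rate_chi_square([[30, 70], [30, 70]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_worked_pearson_value(self):
        chi2, _ = rate_chi_square([[30, 70], [10, 90]])
        assert chi2 == pytest.approx(12.5)

    def test_degenerate_column_raises(self):
        with pytest.raises(DegenerateTableError):
            rate_chi_square([[30, 0], [10, 0]])

    @given(tables)
    @settings(max_examples=300, derandomize=True)
    def test_matches_textbook_formula(self, cells):
        a, b, c, d = cells
        n = a + b + c + d
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        chi2, p = rate_chi_square([[a, b], [c, d]])
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi2 == pytest.approx(expected)
        assert p == pytest.approx(float(chi2_dist.sf(expected, df=1)))


class TestRates:
    @pytest.mark.parametrize(
        "positive, total, expected",
        [(150, 1137, 13.2), (180, 1438, 12.5), (0, 50, 0.0), (1, 3, 33.3)],
    )
    def test_one_decimal_half_up(self, positive, total, expected):
        assert preterm_rate(positive, total) == expected

    def test_half_up_not_bankers(self):
        assert round_half_up(0.25, 1) == 0.3
        assert preterm_rate(1, 8) == 12.5

    def test_zero_total_rejected(self):
        with pytest.raises(DomainError):
            preterm_rate(0, 0)


class TestDifferences:
    def test_signed_difference(self):
        ref = GAEstimate(method=Method.US_7_20, ga_at_birth_days=280)
        later = GAEstimate(method=Method.LMP, ga_at_birth_days=287)
        earlier = GAEstimate(method=Method.LMP, ga_at_birth_days=259)
        assert ga_difference_days(ref, ref) == 0
        assert ga_difference_days(later, ref) == 7
        assert ga_difference_days(earlier, ref) == -21

    @pytest.mark.parametrize(
        "days, category",
        [
            (-15, DiscrepancyCategory.LT_M14),
            (-14, DiscrepancyCategory.M14_TO_M8),
            (-8, DiscrepancyCategory.M14_TO_M8),
            (-7, DiscrepancyCategory.WITHIN_7),
            (0, DiscrepancyCategory.WITHIN_7),
            (7, DiscrepancyCategory.WITHIN_7),
            (8, DiscrepancyCategory.P8_TO_P14),
            (14, DiscrepancyCategory.P8_TO_P14),
            (15, DiscrepancyCategory.GT_P14),
        ],
    )
    def test_category_boundaries(self, days, category):
        assert categorize_difference(days) is category

    def test_categories_partition_the_integers(self):
        for d in range(-100, 101):
            assert categorize_difference(d) in DiscrepancyCategory


class TestStratifiedTable:
    def test_noiseless_cohort_agrees_everywhere(self, noiseless_cohort):
        records, _ = noiseless_cohort
        table, _ = stratified_difference_table(records, Method.LMP, "city")
        populated = table[table.n > 0]
        assert (populated.mean_diff == 0).all()
        assert (populated.pct_within_7 == 100.0).all()

    def test_single_stratum_has_no_p_value(self, noiseless_cohort):
        records, _ = noiseless_cohort
        for r in records:
            r.covariates["city"] = "city_1"
        table, p = stratified_difference_table(records, Method.LMP, "city")
        assert len(table[table.n > 0]) == 1
        assert p is None

    def test_constant_large_shift_lands_in_top_category(self, noiseless_cohort):
        records, _ = noiseless_cohort
        shifted = [
            r.model_copy(update={"capurro_ga_days": r.capurro_ga_days + 20})
            for r in records
        ]
        table, _ = stratified_difference_table(shifted, Method.CAPURRO, "city")
        populated = table[table.n > 0]
        assert (populated.mean_diff == 20).all()
        assert (populated.pct_gt_p14 == 100.0).all()

    def test_empty_stratum_emitted_blank(self, noiseless_cohort):
        records, _ = noiseless_cohort
        table, _ = stratified_difference_table(records, Method.CAPURRO, "ga_at_birth")
        assert set(table.stratum) == {"<=36", "37", "38-39", "40-41", ">=42"}
        empty = table[table.n == 0]
        assert empty.mean_diff.isna().all()


class TestMethodComparisonReport:
    def test_noiseless_cohort_yields_perfect_agreement(
        self, noiseless_cohort, growth_ref
    ):
        records, _ = noiseless_cohort
        report = method_comparison_report(records, growth_ref)
        comparator_rows = report[~report.comparison.str.startswith("reference")]
        assert (comparator_rows.pre_kappa == 1.0).all()
        assert (comparator_rows.pre_sens == 1.0).all()
        assert (comparator_rows.pre_spec == 1.0).all()
        assert (comparator_rows.pre_chi2 == 0.0).all()

    def test_counts_conserved_and_exclusion_shrinks_n(
        self, default_cohort, growth_ref
    ):
        records, _ = default_cohort
        report = method_comparison_report(records, growth_ref)
        class_sum = report.preterm_n + report.term_n + report.postterm_n
        assert (class_sum == report.n).all()
        wide = report.pivot(index="comparison", columns="variant", values="n")
        assert (wide["excluding_outliers"] <= wide["all"]).all()

    def test_certain_lmp_column_is_subset_of_all_lmp(self, default_cohort, growth_ref):
        records, _ = default_cohort
        report = method_comparison_report(records, growth_ref).set_index(
            ["comparison", "variant"]
        )
        assert (
            report.loc[("lmp_sure", "all"), "n"] <= report.loc[("lmp_all", "all"), "n"]
        )

    def test_custom_comparator_identical_to_reference(self, noiseless_cohort, growth_ref):
        records, _ = noiseless_cohort
        report = method_comparison_report(
            records,
            growth_ref,
            comparators=(Comparator("self", Method.US_7_20),),
        ).set_index(["comparison", "variant"])
        row = report.loc[("self", "all")]
        assert row["pre_kappa"] == 1.0 and row["pre_chi2"] == 0.0


class TestGADistributionTable:
    def test_preterm_subtotal_consistent_with_week_rows(self, default_cohort):
        records, _ = default_cohort
        from gestage.dating import gather_estimates

        ga = [
            ests[Method.US_7_20].ga_at_birth_days
            for ests in (gather_estimates(r)[0] for r in records)
            if Method.US_7_20 in ests
        ]
        table = ga_distribution_table(ga)
        week_rows = table[
            table.weeks.isin(["<=29"] + [str(w) for w in range(30, 37)])
        ]
        assert week_rows.n.sum() == table.attrs["preterm_n"]
        assert table.cum_pct.iloc[-1] == 100.0
        assert table.n.sum() == len(ga)

    def test_reconstructed_reference_column_subtotal(self):
        """A GA list reproducing the published per-week reference counts
        gives the printed preterm subtotal of 139 and ends at 100.0%."""
        week_counts = {
            29: 9, 30: 4, 31: 6, 32: 5, 33: 16, 34: 19, 35: 28, 36: 52,
            37: 128, 38: 179, 39: 302, 40: 238, 41: 111, 42: 13, 43: 2,
        }
        ga = [w * 7 for w, n in week_counts.items() for _ in range(n)]
        table = ga_distribution_table(ga)
        assert table.attrs["preterm_n"] == 139
        assert table.attrs["preterm_pct"] == 12.5
        assert table.n.sum() == 1112
        assert table.cum_pct.iloc[-1] == 100.0

    def test_empty_input_gives_empty_table(self):
        table = ga_distribution_table([])
        assert len(table) == 0
        assert table.attrs["preterm_n"] == 0
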