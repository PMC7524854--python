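import numpy as np
import pytest
from scipy import stats as scipy_stats

from lapreg.cohort import (
    CohortRow,
    CohortTable,
    analyze_cohort,
    cohort_from_dataframe,
    load_fixture,
    paired_t,
    read_cohort_csv,
    shapiro_wilk,
    summarize,
    two_sample_t_pooled,
    write_cohort_csv,
)
from lapreg.errors import (
    InsufficientDataError,
    SchemaError,
    UnsupportedSampleSizeError,
)

# The packaged per-patient TRE values (mm RMS), one row per study patient.
PHASE1_MANUAL = [15.4, 22.7, 24.6, 5.9, 16.1, 10.0]
PHASE2_MANUAL = [9.2, 10.6, 17.5, 9.8, 12.5, 16.1, 9.6, 12.9, 2.8, 8.0]
PHASE2_SEMI = [10.4, 8.7, 16.8, 9.8, 20.8, 11.6, 11.1, 16.8, 13.0, 19.9]


@pytest.fixture(scope="module")
def table3():
    return load_fixture("table3")


class TestFixture:
    def test_columns_match_published_values(self, table3):
        np.testing.assert_array_equal(table3.phase1_manual(), PHASE1_MANUAL)
        np.testing.assert_array_equal(table3.phase2_manual(), PHASE2_MANUAL)
        np.testing.assert_array_equal(table3.phase2_semiauto(), PHASE2_SEMI)

    def test_unknown_fixture(self):
        with pytest.raises(SchemaError):
            load_fixture("no_such_table")


class TestSummarize:
    def test_phase2_manual_published_summary(self):
        s = summarize(PHASE2_MANUAL)
        assert (round(s.mean_mm, 1), round(s.sd_mm, 1)) == (10.9, 4.2)
        assert s.rounded() == "10.9 ± 4.2"

    def test_phase1_manual_published_summary(self):
        s = summarize(PHASE1_MANUAL)
        assert (round(s.mean_mm, 1), round(s.sd_mm, 1)) == (15.8, 7.2)

    def test_phase2_semiauto_published_summary(self):
        s = summarize(PHASE2_SEMI)
        assert (round(s.mean_mm, 1), round(s.sd_mm, 1)) == (13.9, 4.4)

    def test_sample_not_population_sd(self):
        # the published 7.2 only reproduces with the n-1 denominator
        assert round(float(np.std(PHASE1_MANUAL, ddof=0)), 1) != 7.2
        assert summarize(PHASE1_MANUAL).sd_mm == pytest.approx(
            np.std(PHASE1_MANUAL, ddof=1)
        )

    def test_constant_list_sd_zero(self):
        assert summarize([4.0, 4.0, 4.0]).sd_mm == 0.0

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            summarize([1.0])


class TestShapiroWilk:
    @pytest.mark.parametrize("values", [PHASE1_MANUAL, PHASE2_MANUAL, PHASE2_SEMI])
    def test_matches_reference_implementation(self, values):
        W, p = shapiro_wilk(values)
        ref = scipy_stats.shapiro(values)
        assert W == pytest.approx(ref.statistic, abs=1e-6)
        assert p == pytest.approx(ref.pvalue, abs=1e-6)

    @pytest.mark.parametrize("n", [4, 7, 12, 25, 50])
    def test_matches_reference_on_random_samples(self, n):
        x = np.random.default_rng(n).gamma(2.0, size=n)
        W, p = shapiro_wilk(x)
        ref = scipy_stats.shapiro(x)
        assert W == pytest.approx(ref.statistic, abs=1e-6)
        assert p == pytest.approx(ref.pvalue, abs=1e-4)

    def test_affine_invariance(self):
        W1, p1 = shapiro_wilk(PHASE2_MANUAL)
        transformed = [3.7 * v + 11.0 for v in PHASE2_MANUAL]
        W2, p2 = shapiro_wilk(transformed)
        assert W2 == pytest.approx(W1, abs=1e-12)
        assert p2 == pytest.approx(p1, abs=1e-12)

    def test_n3_equal_spacing_gives_w1(self):
        W, p = shapiro_wilk([1.0, 2.0, 3.0])
        assert W == pytest.approx(1.0, abs=1e-9)

    def test_unsupported_n(self):
        with pytest.raises(UnsupportedSampleSizeError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(UnsupportedSampleSizeError):
            shapiro_wilk(np.arange(51.0))

    def test_zero_variance(self):
        with pytest.raises(InsufficientDataError):
            shapiro_wilk([5.0, 5.0, 5.0, 5.0])


class TestTwoSampleTPooled:
    def test_published_between_phase_comparison(self):
        r = two_sample_t_pooled(PHASE1_MANUAL, PHASE2_MANUAL)
        assert round(r.estimate_mm, 1) == 4.9
        assert round(r.ci95_mm[0], 1) == -1.1
        assert round(r.ci95_mm[1], 1) == 10.9
        assert round(r.p_two_sided, 3) == 0.104
        assert r.df == 14

    def test_identical_groups(self):
        r = two_sample_t_pooled([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.estimate_mm == 0.0
        assert r.p_two_sided == pytest.approx(1.0)

    def test_hand_computed_textbook_case(self):
        # a=[1,2,3], b=[2,4]: means 2 and 3; pooled var = (2 + 2)/3 = 4/3
        # SE = sqrt(4/3 * (1/3 + 1/2)) = sqrt(10/9); t = -1/sqrt(10/9)
        r = two_sample_t_pooled([1.0, 2.0, 3.0], [2.0, 4.0])
        assert r.estimate_mm == pytest.approx(-1.0)
        assert r.df == 3
        assert r.t_stat == pytest.approx(-1.0 / np.sqrt(10.0 / 9.0))

    def test_antisymmetry(self):
        a, b = PHASE1_MANUAL, PHASE2_MANUAL
        r1, r2 = two_sample_t_pooled(a, b), two_sample_t_pooled(b, a)
        assert r2.estimate_mm == pytest.approx(-r1.estimate_mm)
        assert r2.ci95_mm[0] == pytest.approx(-r1.ci95_mm[1])
        assert r2.p_two_sided == pytest.approx(r1.p_two_sided)

    def test_pooled_equals_welch_t_for_equal_n(self):
        # for equal group sizes the t statistics coincide (dfs differ)
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=8), rng.normal(loc=0.4, size=8)
        r = two_sample_t_pooled(a, b)
        welch = scipy_stats.ttest_ind(a, b, equal_var=False)
        assert r.t_stat == pytest.approx(welch.statistic, abs=1e-12)

    def test_matches_scipy_pooled(self):
        r = two_sample_t_pooled(PHASE1_MANUAL, PHASE2_MANUAL)
        ref = scipy_stats.ttest_ind(PHASE1_MANUAL, PHASE2_MANUAL, equal_var=True)
        assert r.t_stat == pytest.approx(ref.statistic, abs=1e-12)
        assert r.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_variance_flag(self):
        r = two_sample_t_pooled([1.0, 1.0], [2.0, 2.0])
        assert r.p_two_sided == 0.0
        assert np.isinf(r.t_stat)
        assert r.note is not None


class TestPairedT:
    def test_published_within_phase_estimate(self):
        r = paired_t(PHASE2_MANUAL, PHASE2_SEMI)
        assert round(r.estimate_mm, 1) == -3.0
        assert r.df == 9

    def test_identical_lists(self):
        r = paired_t([1.0, 2.0], [1.0, 2.0])
        assert r.estimate_mm == 0.0
        assert r.p_two_sided == pytest.approx(1.0)

    def test_hand_computed_differences(self):
        # d=[1,2,3,4]: mean 2.5, sd sqrt(5/3), t = 2.5 / (sd/2)
        r = paired_t([1.0, 2.0, 3.0, 4.0], [0.0, 0.0, 0.0, 0.0])
        sd = np.sqrt(5.0 / 3.0)
        assert r.t_stat == pytest.approx(2.5 / (sd / 2.0))
        assert r.df == 3

    def test_matches_scipy(self):
        r = paired_t(PHASE2_MANUAL, PHASE2_SEMI)
        ref = scipy_stats.ttest_rel(PHASE2_MANUAL, PHASE2_SEMI)
        assert r.t_stat == pytest.approx(ref.statistic, abs=1e-12)
        assert r.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(SchemaError):
            paired_t([1.0, 2.0], [1.0, 2.0, 3.0])


class TestAnalyzeCohort:
    def test_published_report(self, table3):
        report = analyze_cohort(table3)
        assert report["groups"]["phase1_manual"]["rounded"] == "15.8 ± 7.2"
        assert report["groups"]["phase2_manual"]["rounded"] == "10.9 ± 4.2"
        assert report["groups"]["phase2_semiauto"]["rounded"] == "13.9 ± 4.4"
        t = report["tests"]["manual_phase1_vs_phase2_pooled"]["rounded"]
        assert (t["estimate_mm"], tuple(t["ci95_mm"]), t["p"]) == (4.9, (-1.1, 10.9), 0.104)
        paired = report["tests"]["phase2_manual_vs_semiauto_paired"]["rounded"]
        assert paired["estimate_mm"] == -3.0
        # both variants of the within-phase contrast are reported
        assert "phase2_manual_vs_semiauto_pooled" in report["tests"]

    def test_single_phase_skips_independent_test(self):
        rows = tuple(
            CohortRow(f"P{i}", 2, float(m), float(s))
            for i, (m, s) in enumerate(zip(PHASE2_MANUAL, PHASE2_SEMI))
        )
        report = analyze_cohort(CohortTable(rows))
        assert "manual_phase1_vs_phase2_pooled" not in report["tests"]
        assert any("skipped" in n for n in report["notices"])

    def test_jackknife_bookkeeping(self, table3):
        rows = tuple(r for r in table3.rows if r.patient_id != "LS15")
        report = analyze_cohort(CohortTable(rows))
        assert report["groups"]["phase2_manual"]["n"] == 9
        assert report["groups"]["phase2_semiauto"]["n"] == 9
        assert report["tests"]["phase2_manual_vs_semiauto_paired"]["df"] == 8


class TestSchema:
    def test_phase1_with_semiauto_rejected(self):
        with pytest.raises(SchemaError):
            CohortTable((CohortRow("A", 1, 10.0, 12.0),))

    def test_phase2_missing_value_rejected(self):
        with pytest.raises(SchemaError):
            CohortTable((CohortRow("A", 2, 10.0, None),))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(SchemaError):
            CohortTable((CohortRow("A", 1, 10.0, None), CohortRow("A", 1, 11.0, None)))

    def test_bad_phase_rejected(self):
        with pytest.raises(SchemaError):
            CohortTable((CohortRow("A", 3, 10.0, None),))

    def test_missing_column_message(self):
        import pandas as pd

        with pytest.raises(SchemaError, match="tre_semiauto"):
            cohort_from_dataframe(pd.DataFrame({"patient_id": ["A"], "phase": [1],
                                                "tre_manual": [1.0]}))

    def test_csv_round_trip(self, table3, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort_csv(table3, path)
        again = read_cohort_csv(path)
        assert again == table3
        assert "NA" in path.read_text()
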