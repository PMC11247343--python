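"""Severity classification, characteristics tables, chi-square, yearly trend."""

import math

import pandas as pd
import pytest

from faers_signal.descriptives import (
    age_band,
    assign_outcome_category,
    classify_severity,
    outcome_table,
    pearson_chi_square,
    percentages,
    severity_comparison,
    severity_table,
    summarize_characteristics,
    yearly_trend,
)
from faers_signal.io import deduplicate
from faers_signal.model import DegenerateTableError, ReportSet
from faers_signal.simulate import generate, default_config


class TestSeverity:
    @pytest.mark.parametrize(
        "outcomes,expected",
        [
            ({"HO"}, "serious"),
            ({"DE"}, "serious"),
            ({"LT"}, "serious"),
            ({"DS"}, "serious"),
            ({"OT"}, "non_serious"),
            ({"HO", "OT"}, "serious"),  # serious takes precedence
            (set(), "unknown"),
        ],
    )
    def test_classification(self, mk, outcomes, expected):
        assert classify_severity(mk("a", ["x"], ["pt"], outcomes=outcomes)) == expected

    def test_partition_of_synthetic_cases(self, sim_small):
        _, reports, _ = sim_small
        dedup = deduplicate(reports)
        labels = [classify_severity(r) for r in dedup]
        assert len(labels) == len(dedup)
        counts = pd.Series(labels).value_counts()
        assert counts.sum() == len(dedup)
        assert set(counts.index) <= {"serious", "non_serious", "unknown"}


class TestOutcomeTable:
    def test_death_takes_precedence_over_hospitalization(self, mk):
        r = mk("a", ["x"], ["pt"], outcomes={"DE", "HO"})
        assert assign_outcome_category(r) == "death"

    def test_empty_outcomes_fall_into_unknown(self, mk):
        cases = {"drugx": ReportSet([mk("a", ["x"], ["pt"])])}
        table = outcome_table(cases)
        assert table.loc["unknown", "drugx"] == 1

    def test_columns_sum_to_case_totals(self, sim_small):
        _, reports, _ = sim_small
        dedup = deduplicate(reports)
        cases = {"all": dedup}
        table = outcome_table(cases)
        assert table["all"].sum() == len(dedup)

    def test_matches_brute_force_tally(self, sim_small):
        _, reports, truth = sim_small
        dedup = deduplicate(reports)
        table = outcome_table({"all": dedup})
        code_to_cat = {
            "HO": "hospitalization", "DE": "death", "LT": "life_threatening",
            "DS": "disability", "OT": "others", "none": "unknown",
        }
        expected = pd.Series(
            [code_to_cat[truth.outcome[r.case_id]] for r in dedup]
        ).value_counts()
        for category in table.index:
            assert table.loc[category, "all"] == expected.get(category, 0)

    def test_severity_table_consistent_with_outcome_table(self, sim_small):
        _, reports, _ = sim_small
        dedup = deduplicate(reports)
        cases = {"all": dedup}
        out = outcome_table(cases)["all"]
        sev = severity_table(cases)["all"]
        serious = out[["hospitalization", "death", "life_threatening", "disability"]].sum()
        assert sev["serious"] == serious
        assert sev["non_serious"] == out["others"]
        assert sev["unknown"] == out["unknown"]


class TestCharacteristics:
    def test_age_band_edges_and_median(self, mk):
        cases = {
            "drugx": ReportSet(
                [
                    mk("a", ["x"], ["pt"], age=30),
                    mk("b", ["x"], ["pt"], age=64),
                    mk("c", ["x"], ["pt"], age=65),
                ]
            )
        }
        s = summarize_characteristics(cases)
        assert s.age_bands["drugx"].tolist() == [1, 1, 1, 0]  # <40, 40-64, >=65, unknown
        assert s.age_stats.loc["drugx", "median"] == 64

    def test_all_missing_ages(self, mk):
        cases = {"drugx": ReportSet([mk("a", ["x"], ["pt"]), mk("b", ["x"], ["pt"])])}
        s = summarize_characteristics(cases)
        assert s.age_bands.loc["unknown", "drugx"] == 2
        assert math.isnan(s.age_stats.loc["drugx", "median"])

    def test_category_counts_sum_to_case_totals(self, sim_small):
        _, reports, _ = sim_small
        dedup = deduplicate(reports)
        cases = {"all": dedup}
        s = summarize_characteristics(cases)
        for frame in (s.sex, s.age_bands, s.years, s.countries):
            assert frame["all"].sum() == len(dedup)

    def test_matches_generator_ground_truth(self):
        config = default_config(n_reports=300, seed=41)
        reports, truth = generate(config)
        dedup = deduplicate(reports)
        s = summarize_characteristics({"all": dedup})
        sex_expected = pd.Series([truth.sex[r.case_id] for r in dedup]).value_counts()
        for sex in ("female", "male", "unknown"):
            assert s.sex.loc[sex, "all"] == sex_expected.get(sex, 0)
        band_expected = pd.Series([truth.age_band[r.case_id] for r in dedup]).value_counts()
        for band in ("<40", "40-64", ">=65", "unknown"):
            assert s.age_bands.loc[band, "all"] == band_expected.get(band, 0)
        year_expected = pd.Series([truth.year[r.case_id] for r in dedup]).value_counts()
        for year in year_expected.index:
            assert s.years.loc[year, "all"] == year_expected[year]

    def test_percentages_recompute_from_counts(self, sim_small):
        _, reports, _ = sim_small
        dedup = deduplicate(reports)
        s = summarize_characteristics({"all": dedup})
        pct = percentages(s.sex)
        manual = round(100 * s.sex.loc["female", "all"] / s.sex["all"].sum(), 2)
        assert pct.loc["female", "all"] == manual


class TestPearsonChiSquare:
    def test_agrees_with_hand_computation(self):
        table = pd.DataFrame({"g1": [20, 30], "g2": [40, 10]}, index=["x", "y"])
        res = pearson_chi_square(table)
        observed = table.to_numpy(float)
        row = observed.sum(axis=1, keepdims=True)
        col = observed.sum(axis=0, keepdims=True)
        expected = row @ col / observed.sum()
        manual = ((observed - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(manual, abs=1e-3)
        assert res.df == 1

    def test_two_by_three_hand_computation(self):
        table = pd.DataFrame({"g1": [10, 20, 30], "g2": [15, 12, 33]}, index=["x", "y", "z"])
        res = pearson_chi_square(table)
        observed = table.to_numpy(float)
        expected = observed.sum(1, keepdims=True) @ observed.sum(0, keepdims=True) / observed.sum()
        manual = ((observed - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(manual, abs=1e-3)
        assert res.df == 2

    def test_proportional_table_gives_zero_statistic(self):
        table = pd.DataFrame({"g1": [10, 30], "g2": [20, 60]}, index=["x", "y"])
        res = pearson_chi_square(table)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_drop_categories_removes_rows(self):
        table = pd.DataFrame(
            {"serious": [500, 6, 11], "non_serious": [293, 1, 17]},
            index=["female", "male", "unknown"],
        )
        res = pearson_chi_square(table, drop_categories=["unknown"])
        assert list(res.cells_used.index) == ["female", "male"]
        assert res.df == 1

    def test_degenerate_table_is_an_error(self):
        table = pd.DataFrame({"g1": [5, 0], "g2": [7, 0]}, index=["x", "y"])
        with pytest.raises(DegenerateTableError):
            pearson_chi_square(table)


class TestSeverityComparison:
    def test_tables_built_from_cases(self, mk):
        cases = {
            "drugx": ReportSet(
                [mk(f"s{i}", ["x"], ["pt"], outcomes={"HO"}, sex="female", age=70) for i in range(30)]
                + [mk(f"sm{i}", ["x"], ["pt"], outcomes={"HO"}, sex="male", age=50) for i in range(5)]
                + [mk(f"n{i}", ["x"], ["pt"], outcomes={"OT"}, sex="female", age=30) for i in range(20)]
                + [mk(f"nm{i}", ["x"], ["pt"], outcomes={"OT"}, sex="male", age=55) for i in range(10)]
            )
        }
        res = severity_comparison(cases)
        sex = res["sex"].cells_used
        assert sex.loc["female", "serious"] == 30
        assert sex.loc["male", "non_serious"] == 10
        assert res["sex"].df == 1
        assert res["age"].df == 2


class TestYearlyTrend:
    def test_zero_total_year_reports_missing_proportion(self, mk):
        all_ps = ReportSet([mk("a", ["x"], ["pt"], year=2020)])
        infection = ReportSet([mk("b", ["x"], ["pt"], year=2021)])
        trend = yearly_trend(all_ps, infection).set_index("year")
        assert math.isnan(trend.loc[2021, "proportion"])

    def test_simple_arithmetic(self, mk):
        all_ps = ReportSet([mk(f"a{i}", ["x"], ["pt"], year=2020) for i in range(100)])
        infection = ReportSet([mk("a0", ["x"], ["pt"], year=2020), mk("a1", ["x"], ["pt"], year=2020)])
        trend = yearly_trend(all_ps, infection).set_index("year")
        assert trend.loc[2020, "proportion"] == pytest.approx(0.0200)

    def test_matches_brute_force_per_year_tally(self, sim_small):
        _, reports, _ = sim_small
        dedup = deduplicate(reports)
        half = ReportSet([r for r in dedup if int(r.case_id[1:]) % 2 == 0])
        trend = yearly_trend(dedup, half).set_index("year")
        for year in trend.index:
            total = sum(1 for r in dedup if r.report_year == year)
            infect = sum(1 for r in half if r.report_year == year)
            assert trend.loc[year, "total_ps"] == total
            assert trend.loc[year, "infection_ps"] == infect
            if total:
                assert trend.loc[year, "proportion"] == pytest.approx(round(infect / total, 4))
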