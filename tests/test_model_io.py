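"""Parsing, deduplication, PT→SOC mapping and drug matching."""

import io as stdio
import random

import pytest

from faers_signal.io import (
    deduplicate,
    load_pt_soc_map,
    match_drug,
    parse_reports,
    read_tables,
    write_tables,
)
from faers_signal.model import (
    MappingConflictError,
    ParseError,
    PtSocMap,
    ReportSet,
    version_sort_key,
)
from faers_signal.simulate import default_config, generate


def _tsv(header, rows):
    lines = ["\t".join(header)] + ["\t".join(str(v) for v in row) for row in rows]
    return stdio.StringIO("\n".join(lines) + "\n")


DEMO_HDR = ["case_id", "version_key", "sex", "age_years", "country", "report_year"]


def _streams(demo_rows, drug_rows, reac_rows, outc_rows=()):
    return (
        _tsv(DEMO_HDR, demo_rows),
        _tsv(["case_id", "drug_name", "role_code"], drug_rows),
        _tsv(["case_id", "pt"], reac_rows),
        _tsv(["case_id", "outcome"], outc_rows),
    )


class TestParseReports:
    def test_identity_join_of_three_reports(self):
        reports = parse_reports(
            *_streams(
                [
                    ["a", "2020Q1-1", "female", "60", "us", 2020],
                    ["b", "2020Q2-1", "male", "", "", 2020],
                    ["c", "2021Q1-1", "", "45.5", "germany", 2021],
                ],
                [["a", "palbociclib", "PS"], ["b", "letrozole", "C"], ["c", "ribociclib", "SS"]],
                [["a", "pneumonia"], ["a", "nausea"], ["b", "cough"], ["c", "pneumonia"]],
                [["a", "HO"], ["c", "DE"], ["c", "OT"]],
            ),
            dialect="simple_tsv",
        )
        assert len(reports) == 3
        a = reports.get("a")
        assert a.reactions == ("nausea", "pneumonia")
        assert a.outcomes == {"HO"}
        assert a.sex == "female" and a.age_years == 60 and a.country == "us"
        b = reports.get("b")
        assert b.age_years is None and b.country is None and b.outcomes == frozenset()
        assert reports.get("c").drugs[0].role_code == "SS"

    def test_orphan_reaction_row_logged_and_dropped(self, caplog):
        with caplog.at_level("WARNING"):
            reports = parse_reports(
                *_streams(
                    [["a", "2020Q1-1", "female", "", "", 2020]],
                    [["a", "palbociclib", "PS"]],
                    [["a", "pneumonia"], ["ghost", "cough"]],
                ),
                dialect="simple_tsv",
            )
        assert len(reports) == 1
        assert any("no matching demographics" in r.message for r in caplog.records)

    def test_report_without_reaction_is_dropped(self, caplog):
        with caplog.at_level("WARNING"):
            reports = parse_reports(
                *_streams(
                    [
                        ["a", "2020Q1-1", "female", "", "", 2020],
                        ["b", "2020Q1-1", "female", "", "", 2020],
                    ],
                    [["a", "palbociclib", "PS"], ["b", "palbociclib", "PS"]],
                    [["a", "pneumonia"]],
                ),
                dialect="simple_tsv",
            )
        assert reports.case_ids() == {"a"}

    def test_missing_mandatory_column_names_it(self):
        bad_demo = _tsv(["case_id", "sex"], [["a", "female"]])
        with pytest.raises(ParseError, match="version_key"):
            parse_reports(
                bad_demo,
                _tsv(["case_id", "drug_name", "role_code"], []),
                _tsv(["case_id", "pt"], []),
                _tsv(["case_id", "outcome"], []),
                dialect="simple_tsv",
            )

    def test_empty_demographics_is_an_error(self):
        with pytest.raises(ParseError, match="no rows"):
            parse_reports(*_streams([], [], []), dialect="simple_tsv")

    def test_unknown_dialect_rejected(self):
        with pytest.raises(ParseError, match="dialect"):
            parse_reports(*_streams([], [], []), dialect="csv")

    def test_row_order_invariance(self, tmp_path):
        config = default_config(n_reports=60, seed=5)
        reports, _ = generate(config)
        write_tables(reports, "simple_tsv", tmp_path)
        baseline = read_tables(tmp_path, "simple_tsv")
        rng = random.Random(0)
        for name in ("demo.tsv", "drug.tsv", "reac.tsv", "outc.tsv"):
            path = tmp_path / name
            header, *rows = path.read_text().splitlines()
            rng.shuffle(rows)
            path.write_text("\n".join([header] + rows) + "\n")
        assert read_tables(tmp_path, "simple_tsv") == baseline

    @pytest.mark.parametrize("dialect", ["simple_tsv", "faers_ascii"])
    def test_write_then_parse_round_trip(self, dialect, tmp_path):
        config = default_config(n_reports=50, seed=9)
        reports, _ = generate(config)
        write_tables(reports, dialect, tmp_path)
        assert read_tables(tmp_path, dialect) == reports

    def test_faers_dialect_is_dollar_delimited(self, tmp_path):
        reports, _ = generate(default_config(n_reports=5, seed=1))
        paths = write_tables(reports, "faers_ascii", tmp_path)
        for path in paths:
            header = path.read_text().splitlines()[0]
            assert "$" in header

    def test_faers_age_unit_conversion(self):
        demo = stdio.StringIO(
            "primaryid$caseid$caseversion$fda_dt$sex$age$age_cod$occr_country\n"
            "a.1$a$1$20200215$F$730.5$DY$US\n"
            "b.1$b$1$20200515$M$18$MON$\n"
            "c.1$c$1$20210815$F$7$DEC$DE\n"
        )
        drug = stdio.StringIO("primaryid$role_cod$drugname\na.1$PS$x\nb.1$PS$x\nc.1$PS$x\n")
        reac = stdio.StringIO("primaryid$pt\na.1$cough\nb.1$cough\nc.1$cough\n")
        outc = stdio.StringIO("primaryid$outc_cod\n")
        reports = parse_reports(demo, drug, reac, outc, dialect="faers_ascii")
        assert reports.get("a").age_years == pytest.approx(2.0)
        assert reports.get("b").age_years == pytest.approx(1.5)
        assert reports.get("c").age_years == pytest.approx(70.0)
        assert reports.get("a").quarter == "2020Q1"
        assert reports.get("b").quarter == "2020Q2"


class TestDeduplicate:
    def test_highest_version_survives(self, mk):
        older = mk("A", ["x"], ["pty"], version="2020Q1-1")
        newer = mk("A", ["x"], ["ptz"], version="2020Q3-2")
        result = deduplicate(ReportSet([newer, older]))
        assert len(result) == 1
        assert result.get("A").reactions == ("ptz",)

    def test_all_unique_unchanged(self, toy_reports):
        assert deduplicate(toy_reports) == toy_reports

    def test_sequence_numbers_compare_numerically(self, mk):
        v2 = mk("A", ["x"], ["a"], version="2020Q1-2")
        v10 = mk("A", ["x"], ["b"], version="2020Q1-10")
        assert deduplicate(ReportSet([v10, v2])).get("A").reactions == ("b",)
        assert version_sort_key("2020Q1-10") > version_sort_key("2020Q1-2")

    def test_idempotent(self, sim_small):
        _, reports, _ = sim_small
        once = deduplicate(reports)
        assert deduplicate(once) == once

    def test_planted_duplicates_against_brute_force(self):
        config = default_config(n_reports=100, seed=23)
        reports, truth = generate(config)
        result = deduplicate(reports)
        assert len(result) == 100  # one survivor per generated case
        # brute-force group-by scan
        by_case = {}
        for idx, r in enumerate(reports):
            key = (version_sort_key(r.version_key), idx)
            if r.case_id not in by_case or key > by_case[r.case_id][0]:
                by_case[r.case_id] = (key, r)
        for case_id, (_, expected) in by_case.items():
            assert result.get(case_id) == expected
        for case_id in truth.duplicated_case_ids:
            assert result.get(case_id).version_key.endswith("-2")


class TestPtSocMap:
    def test_lookup_is_case_insensitive(self):
        m = load_pt_soc_map(_tsv(["pt", "soc"], [["pneumonia", "Infections and Infestations"]]))
        assert m.get("Pneumonia") == "infections and infestations"
        assert "PNEUMONIA" in m

    def test_conflicting_duplicate_is_an_error(self):
        rows = [["pneumonitis", "soc one"], ["Pneumonitis", "soc two"]]
        with pytest.raises(MappingConflictError, match="pneumonitis"):
            load_pt_soc_map(_tsv(["pt", "soc"], rows))

    def test_consistent_duplicate_is_fine(self):
        rows = [["pneumonia", "infections"], ["PNEUMONIA", "Infections"]]
        assert len(load_pt_soc_map(_tsv(["pt", "soc"], rows))) == 1

    def test_thirty_entries_round_trip(self):
        socs = ["soc a", "soc b", "soc c", "soc d"]
        pairs = [(f"term {i}", socs[i % 4]) for i in range(30)]
        m = PtSocMap(pairs)
        assert len(m) == 30
        for pt, soc in pairs:
            assert m.get(pt.upper()) == soc


class TestMatchDrug:
    def test_case_folded_equality(self, mk):
        r = mk("a", [("PALBOCICLIB", "PS")], ["x"])
        assert match_drug(r, ["palbociclib", "ibrance"])

    def test_no_substring_matching(self, mk):
        r = mk("a", [("palbociclib tablet", "PS")], ["x"])
        assert not match_drug(r, ["palbociclib"])

    def test_empty_synonym_list_rejected(self, mk):
        with pytest.raises(ValueError):
            match_drug(mk("a", ["x"], ["y"]), [])

    def test_agrees_with_generator_ground_truth(self):
        config = default_config(n_reports=200, seed=29)
        reports, truth = generate(config)
        for r in deduplicate(reports):
            for drug in ("palbociclib", "ribociclib", "abemaciclib"):
                assert match_drug(r, [drug]) == (drug in truth.drugs[r.case_id])
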