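"""Parsing, deduplication and standardization of FAERS-dialect tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pvscreen.faers_io import (
    FaersFormatError,
    TermMap,
    deduplicate_reports,
    frame_to_reports,
    load_term_map,
    parse_quarter_tables,
    read_cohort,
    standardize_terms,
    write_cohort,
)


class TestParseQuarterTables:
    def test_header_only_tables_yield_empty_cohort(self, tmp_path, quarter_writer):
        paths = quarter_writer(tmp_path, [], [], [])
        cohort = parse_quarter_tables(paths)
        assert cohort.empty

    def test_join_attaches_matching_drug_and_reac_rows(self, tmp_path, quarter_writer):
        paths = quarter_writer(
            tmp_path,
            demo_rows=[
                "100$10$20200101$45$YR$M$CN$US",
                "200$20$20200202$72$YR$F$MD$GB",
            ],
            drug_rows=[
                "100$10$1$PS$LIPITOR",
                "100$10$2$C$ASPIRIN",
                "200$20$1$PS$CRESTOR",
            ],
            reac_rows=["100$10$Erectile dysfunction", "200$20$Nausea"],
        )
        cohort = parse_quarter_tables(paths)
        assert len(cohort) == 2
        by_id = cohort.set_index("primaryid")
        assert by_id.loc[100, "drugs_raw"].count("|") + 1 == 2
        assert by_id.loc[200, "drugs_raw"].count("|") + 1 == 1
        assert by_id.loc[100, "drug_roles"] == "PS|C"
        assert by_id.loc[100, "age_group"] == "18-64"
        assert by_id.loc[200, "age_group"] == "65-85"
        assert by_id.loc[200, "reporter"] == "physician"
        assert by_id.loc[200, "country"] == "gb"

    def test_all_seven_tables_parsed_and_attached(self, tmp_path, quarter_writer):
        paths = quarter_writer(
            tmp_path,
            demo_rows=["100$10$20200101$45$YR$M$CN$US"],
            drug_rows=["100$10$1$PS$LIPITOR"],
            reac_rows=["100$10$Nausea"],
            outc=["100$10$HO", "100$10$DE"],
            rpsr=["100$10$FGN"],
            ther=["100$10$1$20190101$20190301"],
            indi=["100$10$1$Hypertension"],
        )
        cohort = parse_quarter_tables(paths)
        row = cohort.iloc[0]
        assert set(row["outcomes"].split("|")) == {"hospitalization", "death"}
        assert row["report_sources"] == "FGN"
        assert row["therapy_dates"] == "20190101:20190301"
        assert row["indications"] == "Hypertension"

    def test_demo_rows_without_drug_or_reac_are_dropped(self, tmp_path, quarter_writer):
        paths = quarter_writer(
            tmp_path,
            demo_rows=["100$10$20200101$$$$$", "200$20$20200101$$$$$"],
            drug_rows=["100$10$1$PS$LIPITOR"],
            reac_rows=["100$10$Nausea"],
        )
        cohort = parse_quarter_tables(paths)
        assert cohort["primaryid"].tolist() == [100]

    def test_missing_demo_is_fatal(self, tmp_path, quarter_writer):
        paths = quarter_writer(tmp_path, [], [], [])
        del paths["demo"]
        with pytest.raises(FaersFormatError, match="DEMO"):
            parse_quarter_tables(paths)

    def test_malformed_header_names_the_column(self, tmp_path, quarter_writer):
        paths = quarter_writer(tmp_path, [], [], [])
        (tmp_path / "DEMO.txt").write_text("primaryid$caseid$other\n", encoding="utf-8")
        with pytest.raises(FaersFormatError, match="fda_dt"):
            parse_quarter_tables(paths)

    def test_unparseable_date_becomes_zero(self, tmp_path, quarter_writer):
        paths = quarter_writer(
            tmp_path,
            demo_rows=["100$10$20201350$$$$$"],  # month 13, day 50
            drug_rows=["100$10$1$PS$LIPITOR"],
            reac_rows=["100$10$Nausea"],
        )
        cohort = parse_quarter_tables(paths)
        assert cohort.loc[0, "fda_dt"] == 0
        assert cohort.loc[0, "year"] == 0

    @pytest.mark.parametrize(
        "age,unit,expected",
        [
            ("45", "YR", "18-64"),
            ("4.5", "DEC", "18-64"),
            ("540", "MON", "18-64"),
            ("12", "YR", "<18"),
            ("85", "YR", "65-85"),
            ("86", "YR", ">85"),
            ("", "", "unknown"),
            ("abc", "YR", "unknown"),
        ],
    )
    def test_age_unit_conversion_and_binning(self, tmp_path, quarter_writer, age, unit, expected):
        paths = quarter_writer(
            tmp_path,
            demo_rows=[f"100$10$20200101${age}${unit}$M$CN$US"],
            drug_rows=["100$10$1$PS$LIPITOR"],
            reac_rows=["100$10$Nausea"],
        )
        cohort = parse_quarter_tables(paths)
        assert cohort.loc[0, "age_group"] == expected


class TestDeduplicateReports:
    def test_most_recent_receipt_date_wins(self, cohort_builder):
        cohort = cohort_builder(
            [
                {"primaryid": 1, "caseid": 9, "fda_dt": 20200101},
                {"primaryid": 2, "caseid": 9, "fda_dt": 20210101},
            ]
        )
        out = deduplicate_reports(cohort)
        assert out["primaryid"].tolist() == [2]

    def test_equal_dates_break_to_higher_primaryid(self, cohort_builder):
        cohort = cohort_builder(
            [
                {"primaryid": 100, "caseid": 9, "fda_dt": 20200101},
                {"primaryid": 200, "caseid": 9, "fda_dt": 20200101},
            ]
        )
        assert deduplicate_reports(cohort)["primaryid"].tolist() == [200]

    def test_missing_date_loses_to_any_dated_version(self, cohort_builder):
        cohort = cohort_builder(
            [
                {"primaryid": 500, "caseid": 9, "fda_dt": 0},
                {"primaryid": 2, "caseid": 9, "fda_dt": 20050101},
            ]
        )
        assert deduplicate_reports(cohort)["primaryid"].tolist() == [2]

    def test_distinct_caseids_pass_through(self, cohort_builder):
        cohort = cohort_builder([{"caseid": i} for i in range(1, 6)])
        out = deduplicate_reports(cohort)
        assert sorted(out["primaryid"]) == sorted(cohort["primaryid"])

    def test_idempotent_and_size_equals_distinct_caseids(self, cohort_builder):
        rng = np.random.default_rng(3)
        cohort = cohort_builder(
            [
                {"primaryid": int(pid), "caseid": int(rng.integers(1, 20)),
                 "fda_dt": int(rng.choice([0, 20200101, 20210101, 20220101]))}
                for pid in rng.permutation(1000)[:200]
            ]
        )
        once = deduplicate_reports(cohort)
        twice = deduplicate_reports(once)
        assert once.equals(twice)
        assert len(once) == cohort["caseid"].nunique()

    @settings(derandomize=True, max_examples=30)
    @given(perm_seed=st.integers(0, 10_000))
    def test_order_invariance(self, perm_seed):
        from conftest import make_cohort

        rng = np.random.default_rng(7)
        cohort = make_cohort(
            [
                {"primaryid": int(pid), "caseid": int(rng.integers(1, 10)),
                 "fda_dt": int(rng.choice([0, 20200101, 20210101]))}
                for pid in range(1, 40)
            ]
        )
        shuffled = cohort.sample(frac=1, random_state=perm_seed).reset_index(drop=True)
        a = deduplicate_reports(cohort).sort_values("caseid").reset_index(drop=True)
        b = deduplicate_reports(shuffled).sort_values("caseid").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestStandardizeTerms:
    @pytest.fixture
    def term_map(self):
        return TermMap(
            drug_synonyms={"lipitor": "atorvastatin", "CRESTOR": "rosuvastatin"},
            event_terms=frozenset(["erectile dysfunction"]),
        )

    def test_synonym_lookup_is_case_insensitive(self, cohort_builder, term_map):
        cohort = cohort_builder([{"drugs_raw": "LIPITOR", "drugs_norm": ""}])
        out = standardize_terms(cohort, term_map)
        assert out.loc[0, "drugs_norm"] == "atorvastatin"

    def test_unmapped_names_kept_lowercase_and_counted(self, cohort_builder, term_map):
        cohort = cohort_builder(
            [{"drugs_raw": "MYSTERYDRUG|LIPITOR", "drug_roles": "PS|SS", "drugs_norm": ""}]
        )
        out = standardize_terms(cohort, term_map)
        assert out.loc[0, "drugs_norm"] == "mysterydrug|atorvastatin"
        assert out.attrs["n_unmapped_drugs"] == 1

    def test_event_flag_matches_terms_case_insensitively(self, cohort_builder, term_map):
        cohort = cohort_builder(
            [
                {"reactions": "Erectile dysfunction"},
                {"reactions": "Nausea|ERECTILE DYSFUNCTION"},
                {"reactions": "Nausea"},
            ]
        )
        out = standardize_terms(cohort, term_map)
        assert out["is_target_event"].tolist() == [True, True, False]

    def test_empty_event_terms_is_fatal(self, cohort_builder):
        tm = TermMap(drug_synonyms={}, event_terms=frozenset())
        with pytest.raises(ValueError, match="event"):
            standardize_terms(cohort_builder([{}]), tm)

    def test_record_view_retains_unmapped_names_lowercased(
        self, cohort_builder, term_map
    ):
        cohort = cohort_builder([{"drugs_raw": "LIPITOR|ODDBALL", "drug_roles": "PS|SS"}])
        out = standardize_terms(cohort, term_map)
        reports = frame_to_reports(out)
        assert reports[0].drugs[0].normalized_name == "atorvastatin"
        assert reports[0].drugs[1].normalized_name == "oddball"


class TestTermMapFiles:
    def test_load_term_map_round_trip(self, tmp_path):
        (tmp_path / "syn.tsv").write_text(
            "# comment\nLIPITOR\tatorvastatin\n  CRESTOR \trosuvastatin\n", encoding="utf-8"
        )
        (tmp_path / "events.txt").write_text("Erectile dysfunction\n", encoding="utf-8")
        tm = load_term_map(tmp_path / "syn.tsv", tmp_path / "events.txt")
        assert tm.normalize_drug(" lipitor ") == "atorvastatin"
        assert tm.normalize_drug("crestor") == "rosuvastatin"
        assert tm.is_target(["ERECTILE DYSFUNCTION"])

    def test_malformed_synonym_line_raises(self, tmp_path):
        (tmp_path / "syn.tsv").write_text("justoneword\n", encoding="utf-8")
        (tmp_path / "events.txt").write_text("x\n", encoding="utf-8")
        with pytest.raises(FaersFormatError):
            load_term_map(tmp_path / "syn.tsv", tmp_path / "events.txt")


def test_cohort_flat_file_round_trip(tmp_path, cohort_builder):
    cohort = cohort_builder(
        [
            {"drugs_raw": "A|B", "drug_roles": "PS|C", "drugs_norm": "a|b",
             "reactions": "Nausea|Rash", "outcomes": "death", "is_target_event": True},
            {"fda_dt": 0, "year": 0},
        ]
    )
    write_cohort(cohort, tmp_path / "cohort.tsv")
    back = read_cohort(tmp_path / "cohort.tsv")
    pd.testing.assert_frame_equal(cohort, back)
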