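"""File reading, deduplication, drug filtering and age banding."""

import gzip
import logging

import pandas as pd
import pytest

from pvsignal import (
    AgeBand,
    CaseReport,
    CaseReportSet,
    DrugEntry,
    DrugLexicon,
    ParseError,
    ValidationError,
    assign_age_band,
    assign_age_bands,
    deduplicate_cases,
    filter_target_drug,
    read_faers_tables,
)
from conftest import write_faers_fixture


@pytest.fixture
def three_case_files(tmp_path):
    """Three cases, 5 DRUG rows, 4 REAC rows; joins enumerable by hand."""
    demo = [
        {"primaryid": "101", "caseid": "1", "caseversion": "1", "age": "18", "age_cod": "YR", "sex": "F", "occr_country": "US"},
        {"primaryid": "201", "caseid": "2", "caseversion": "1", "age": "216", "age_cod": "MON", "sex": "M", "occr_country": "DE"},
        {"primaryid": "301", "caseid": "3", "caseversion": "1", "age": "", "age_cod": "", "sex": "", "occr_country": ""},
    ]
    drug = [
        {"primaryid": "101", "caseid": "1", "drugname": "tramadol", "role_cod": "PS"},
        {"primaryid": "101", "caseid": "1", "drugname": "ibuprofen", "role_cod": "C"},
        {"primaryid": "201", "caseid": "2", "drugname": "Ultram", "role_cod": "SS"},
        {"primaryid": "301", "caseid": "3", "drugname": "oxycodone", "role_cod": "PS"},
        {"primaryid": "301", "caseid": "3", "drugname": "TRAMADOL ", "role_cod": "C"},
    ]
    reac = [
        {"primaryid": "101", "caseid": "1", "pt": "Nausea"},
        {"primaryid": "101", "caseid": "1", "pt": "Dizziness"},
        {"primaryid": "201", "caseid": "2", "pt": "Headache"},
        {"primaryid": "301", "caseid": "3", "pt": "Rash"},
    ]
    outc = [
        {"primaryid": "101", "caseid": "1", "outc_cod": "HO"},
        {"primaryid": "201", "caseid": "2", "outc_cod": "DE"},
    ]
    return write_faers_fixture(tmp_path, demo, drug, reac, outc)


class TestReadFaersTables:
    def test_joins_enumerated_by_hand(self, three_case_files):
        cases = read_faers_tables(*[three_case_files[k] for k in ("DEMO", "DRUG", "REAC", "OUTC")])
        reports = {r.case_id: r for r in cases.to_reports()}
        assert set(reports) == {"1", "2", "3"}
        assert len(reports["1"].drugs) == 2 and len(reports["1"].reactions) == 2
        assert reports["1"].outcomes == ["HO"]
        assert reports["2"].drugs == [DrugEntry("Ultram", "SS")]
        assert reports["3"].reactions == ["Rash"] and reports["3"].outcomes == []

    def test_empty_reac_drops_everything(self, tmp_path, three_case_files, caplog):
        sub = tmp_path / "empty"
        sub.mkdir()
        empty = write_faers_fixture(sub, [], [], [], [])
        with caplog.at_level(logging.WARNING):
            cases = read_faers_tables(
                three_case_files["DEMO"], three_case_files["DRUG"], empty["REAC"], three_case_files["OUTC"]
            )
        assert cases.n_versions == 0
        assert "no reaction rows" in caplog.text

    def test_header_only_files(self, tmp_path):
        paths = write_faers_fixture(tmp_path, [], [], [], [])
        cases = read_faers_tables(paths["DEMO"], paths["DRUG"], paths["REAC"], paths["OUTC"])
        assert cases.n_versions == 0

    def test_missing_column_names_file(self, tmp_path, three_case_files):
        bad = tmp_path / "bad_demo.txt"
        bad.write_text("primaryid$caseid\n101$1\n")
        with pytest.raises(ParseError, match="bad_demo"):
            read_faers_tables(bad, three_case_files["DRUG"], three_case_files["REAC"], three_case_files["OUTC"])

    def test_blank_pts_dropped(self, tmp_path, three_case_files, caplog):
        reac = tmp_path / "REAC2.txt"
        reac.write_text("primaryid$caseid$pt\n101$1$Nausea\n201$2$  \n")
        with caplog.at_level(logging.WARNING):
            cases = read_faers_tables(
                three_case_files["DEMO"], three_case_files["DRUG"], reac, three_case_files["OUTC"]
            )
        # case 2's only PT was blank, so the whole report is dropped
        assert set(cases.demo["caseid"]) == {"1"}
        assert "blank PT" in caplog.text

    def test_gzip_supported(self, tmp_path, three_case_files):
        gz_paths = {}
        for name, path in three_case_files.items():
            gz = tmp_path / f"{name}.txt.gz"
            with open(path, "rb") as src, gzip.open(gz, "wb") as dst:
                dst.write(src.read())
            gz_paths[name] = gz
        plain = read_faers_tables(*[three_case_files[k] for k in ("DEMO", "DRUG", "REAC", "OUTC")])
        zipped = read_faers_tables(*[gz_paths[k] for k in ("DEMO", "DRUG", "REAC", "OUTC")])
        pd.testing.assert_frame_equal(plain.demo, zipped.demo)

    def test_dangling_rows_warn_not_fatal(self, tmp_path, three_case_files, caplog):
        drug = tmp_path / "DRUG2.txt"
        drug.write_text(
            "primaryid$caseid$drugname$role_cod\n101$1$tramadol$PS\n999$9$ghost$PS\n201$2$Ultram$SS\n301$3$oxycodone$PS\n"
        )
        with caplog.at_level(logging.WARNING):
            cases = read_faers_tables(
                three_case_files["DEMO"], drug, three_case_files["REAC"], three_case_files["OUTC"]
            )
        assert cases.n_versions == 3
        assert "dangling" in caplog.text


def _versions(*pairs):
    return CaseReportSet.from_reports(
        [
            CaseReport(cid, v, 40, "YR", "F", "US", [DrugEntry("tramadol", "PS")], ["Nausea"], [])
            for cid, v in pairs
        ]
    )


class TestDeduplication:
    def test_keeps_most_recent_version(self):
        out = deduplicate_cases(_versions(("ID1", 1), ("ID1", 2), ("ID2", 1)))
        kept = {(r.case_id, r.version_stamp) for r in out.to_reports()}
        assert kept == {("ID1", 2), ("ID2", 1)}

    def test_identity_without_duplicates(self):
        cases = _versions(("A", 1), ("B", 3))
        out = deduplicate_cases(cases)
        pd.testing.assert_frame_equal(
            out.demo.reset_index(drop=True), cases.demo.sort_values("caseid").reset_index(drop=True)
        )

    def test_idempotent_and_counts_distinct_ids(self):
        cases = _versions(("A", 1), ("A", 2), ("A", 5), ("B", 1), ("C", 2), ("C", 3))
        once = deduplicate_cases(cases)
        twice = deduplicate_cases(once)
        assert once.n_versions == cases.n_cases == 3
        pd.testing.assert_frame_equal(once.demo, twice.demo)

    def test_tied_stamps_keep_greatest_primaryid(self, caplog):
        cases = _versions(("A", 1))
        dup = cases.demo.copy()
        dup.loc[0, "primaryid"] = "A99"  # same caseid + version, different primaryid
        tied = CaseReportSet(
            pd.concat([cases.demo, dup], ignore_index=True), cases.drugs, cases.reactions, cases.outcomes
        )
        with caplog.at_level(logging.WARNING):
            out = deduplicate_cases(tied)
        assert list(out.demo["primaryid"]) == ["A99"]
        assert "tied version stamps" in caplog.text


class TestTargetDrugFilter:
    def test_concomitant_only_excluded(self, six_case_universe, tramadol_lexicon):
        out = filter_target_drug(six_case_universe, tramadol_lexicon)
        # N3 lists tramadol only as C; T2 has the brand synonym Ultram as SS
        assert set(out.demo["caseid"]) == {"T1", "T2", "T3"}

    def test_brand_synonym_primary_suspect_retained(self, tramadol_lexicon):
        cases = CaseReportSet.from_reports(
            [CaseReport("X", 1, 50, "YR", "F", "US", [DrugEntry("ULTRAM ER", "PS")], ["Nausea"], [])]
        )
        assert filter_target_drug(cases, tramadol_lexicon).n_versions == 1

    def test_empty_allowed_roles(self, six_case_universe, tramadol_lexicon):
        assert filter_target_drug(six_case_universe, tramadol_lexicon, allowed_roles=()).n_versions == 0

    def test_widening_roles_is_monotone(self, six_case_universe, tramadol_lexicon):
        narrow = filter_target_drug(six_case_universe, tramadol_lexicon, allowed_roles=("PS", "SS"))
        wide = filter_target_drug(six_case_universe, tramadol_lexicon, allowed_roles=("PS", "SS", "C", "I"))
        assert set(narrow.demo["caseid"]) <= set(wide.demo["caseid"])
        assert "N3" in set(wide.demo["caseid"])

    def test_match_metadata_recorded(self, six_case_universe, tramadol_lexicon):
        _, matches = filter_target_drug(six_case_universe, tramadol_lexicon, return_matches=True)
        assert set(zip(matches["caseid"], matches["role_cod"])) == {("T1", "PS"), ("T2", "SS"), ("T3", "PS")}

    def test_whitespace_and_case_insensitive(self, three_case_files=None):
        lex = DrugLexicon("tramadol", {"Tramadol HCL"})
        assert lex.matches("  tramadol hcl ")


class TestAgeBanding:
    @pytest.mark.parametrize(
        "value, unit, band",
        [
            (18, "YR", AgeBand.CHILD_ADOLESCENT),
            (19, "YR", AgeBand.ADULT),
            (64, "YR", AgeBand.ADULT),
            (65, "YR", AgeBand.OLDER_ADULT),
            (216, "MON", AgeBand.CHILD_ADOLESCENT),  # 216/12 = 18 years
            (230, "MON", AgeBand.ADULT),
            (400, "DY", AgeBand.CHILD_ADOLESCENT),
            (None, None, AgeBand.UNKNOWN),
        ],
    )
    def test_banding(self, value, unit, band):
        assert assign_age_band(value, unit) is band

    def test_negative_age_rejected(self):
        with pytest.raises(ValidationError):
            assign_age_band(-1, "YR")

    def test_unknown_unit_code_is_unknown_band(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert assign_age_band(40, "DEC") is AgeBand.UNKNOWN
        assert "unknown age unit" in caplog.text

    def test_vectorised_matches_scalar(self):
        demo = pd.DataFrame(
            {
                "age": ["18", "19", "64", "65", "216", "", "30"],
                "age_cod": ["YR", "YR", "YR", "YR", "MON", "", "WK"],
            }
        )
        bands = assign_age_bands(demo)
        expected = [
            assign_age_band(None if a == "" else float(a), u or None).value
            for a, u in zip(demo["age"], demo["age_cod"])
        ]
        assert list(bands) == expected
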