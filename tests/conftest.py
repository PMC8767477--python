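"""Shared fixtures: hand-built case universes and terminology fixtures."""

import pandas as pd
import pytest

from pvsignal import CaseReport, CaseReportSet, DrugEntry, DrugLexicon, SymptomLexicon
from pvsignal.resources import DEFAULT_PHRASE_LEXICON, PT_TO_SOC, TRAMADOL_SYNONYMS


@pytest.fixture
def tramadol_lexicon():
    return DrugLexicon("tramadol", set(TRAMADOL_SYNONYMS["tramadol"]))


@pytest.fixture
def phrase_lexicon():
    return SymptomLexicon(dict(DEFAULT_PHRASE_LEXICON))


@pytest.fixture
def soc_map():
    return dict(PT_TO_SOC)


@pytest.fixture
def six_case_universe():
    """Six hand-written cases: three with tramadol as a suspect drug.

    Nausea appears in two target cases and one comparator case (listed
    twice there, which still counts once), giving the 2x2 table (2,1,1,2).
    """
    reports = [
        CaseReport("T1", 1, 30, "YR", "F", "US",
                   [DrugEntry("tramadol", "PS")], ["Nausea", "Dizziness"], ["HO"]),
        CaseReport("T2", 1, 45, "YR", "M", "DE",
                   [DrugEntry("Ultram", "SS"), DrugEntry("ibuprofen", "C")], ["Nausea"], []),
        CaseReport("T3", 1, 60, "YR", "F", "US",
                   [DrugEntry("tramadol", "PS")], ["Headache"], ["DE"]),
        CaseReport("N1", 1, 25, "YR", "M", "GB",
                   [DrugEntry("ibuprofen", "PS")], ["Nausea", "Nausea"], []),
        CaseReport("N2", 1, 70, "YR", "F", "FR",
                   [DrugEntry("oxycodone", "PS")], ["Rash"], []),
        CaseReport("N3", 1, None, None, None, None,
                   [DrugEntry("codeine", "PS"), DrugEntry("tramadol", "C")], ["Headache"], []),
    ]
    return CaseReportSet.from_reports(reports)


@pytest.fixture
def six_case_target(six_case_universe):
    keep = six_case_universe.demo["caseid"].isin(["T1", "T2", "T3"])
    return six_case_universe.subset_primaryids(six_case_universe.demo.loc[keep, "primaryid"])


def write_faers_fixture(directory, demo_rows, drug_rows, reac_rows, outc_rows):
    """Write "$"-delimited table files from lists of row dicts."""
    from pvsignal.types import DEMO_COLUMNS, DRUG_COLUMNS, OUTC_COLUMNS, REAC_COLUMNS

    paths = {}
    for name, rows, cols in [
        ("DEMO", demo_rows, DEMO_COLUMNS),
        ("DRUG", drug_rows, DRUG_COLUMNS),
        ("REAC", reac_rows, REAC_COLUMNS),
        ("OUTC", outc_rows, OUTC_COLUMNS),
    ]:
        path = directory / f"{name}.txt"
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="$", index=False)
        paths[name] = path
    return paths
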