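"""Core data containers for spontaneous-report analysis.

A *case report* is one spontaneous adverse-event report: demographics, the
drugs involved (each with a suspect-role code), the reaction preferred terms
(PTs) and outcome codes. Reports are keyed by a case id; resubmissions of the
same case share the case id and carry a monotonically increasing version
stamp. In-memory, a collection of reports is held as four aligned pandas
DataFrames mirroring the DEMO/DRUG/REAC/OUTC quarterly file layout, joined by
a primary identifier unique to each (case id, version) pair.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: Drug role codes: primary suspect, secondary suspect, concomitant, interacting.
ROLE_CODES = ("PS", "SS", "C", "I")

#: Outcome codes: death, life-threatening, hospitalization, disability,
#: congenital anomaly, required intervention, other.
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

#: Outcomes classed as serious: death, life-threat, hospitalization, disability.
SERIOUS_OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS"})

DEMO_COLUMNS = ["primaryid", "caseid", "caseversion", "age", "age_cod", "sex", "occr_country"]
DRUG_COLUMNS = ["primaryid", "caseid", "drugname", "role_cod"]
REAC_COLUMNS = ["primaryid", "caseid", "pt"]
OUTC_COLUMNS = ["primaryid", "caseid", "outc_cod"]


class AgeBand(str, enum.Enum):
    """Age groups used throughout: <19 y, 19-64 y, >=65 y, or unknown."""

    CHILD_ADOLESCENT = "CHILD_ADOLESCENT"
    ADULT = "ADULT"
    OLDER_ADULT = "OLDER_ADULT"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class DrugEntry:
    """One drug row of a report: verbatim name plus its suspect-role code."""

    drug_name_verbatim: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLE_CODES:
            raise ValueError(f"unknown drug role code {self.role!r}; expected one of {ROLE_CODES}")


@dataclass
class CaseReport:
    """One spontaneous report (a single version of a case)."""

    case_id: str
    version_stamp: int
    age_value: Optional[float] = None
    age_unit: Optional[str] = None  # YR / MON / DY
    sex: Optional[str] = None  # F / M / None (unknown)
    country: Optional[str] = None
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)
    outcomes: list[str] = field(default_factory=list)

    @property
    def primary_id(self) -> str:
        return f"{self.case_id}-{self.version_stamp}"


def _empty(columns: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


@dataclass
class CaseReportSet:
    """A collection of report versions as DEMO/DRUG/REAC/OUTC tables.

    ``demo`` has one row per (case id, version); the other three tables join
    to it on ``primaryid``. Values are stored as strings (the file dialect),
    with missing demographics as empty strings.
    """

    demo: pd.DataFrame
    drugs: pd.DataFrame
    reactions: pd.DataFrame
    outcomes: pd.DataFrame

    @classmethod
    def empty(cls) -> "CaseReportSet":
        return cls(_empty(DEMO_COLUMNS), _empty(DRUG_COLUMNS), _empty(REAC_COLUMNS), _empty(OUTC_COLUMNS))

    # -- construction / deconstruction -------------------------------------

    @classmethod
    def from_reports(cls, reports: Iterable[CaseReport]) -> "CaseReportSet":
        demo_rows, drug_rows, reac_rows, outc_rows = [], [], [], []
        for r in reports:
            pid = r.primary_id
            demo_rows.append(
                {
                    "primaryid": pid,
                    "caseid": r.case_id,
                    "caseversion": str(r.version_stamp),
                    "age": "" if r.age_value is None else format(r.age_value, "g"),
                    "age_cod": r.age_unit or "",
                    "sex": r.sex or "",
                    "occr_country": r.country or "",
                }
            )
            for d in r.drugs:
                drug_rows.append(
                    {"primaryid": pid, "caseid": r.case_id, "drugname": d.drug_name_verbatim, "role_cod": d.role}
                )
            for pt in r.reactions:
                reac_rows.append({"primaryid": pid, "caseid": r.case_id, "pt": pt})
            for oc in r.outcomes:
                outc_rows.append({"primaryid": pid, "caseid": r.case_id, "outc_cod": oc})
        return cls(
            pd.DataFrame(demo_rows, columns=DEMO_COLUMNS).astype(object) if demo_rows else _empty(DEMO_COLUMNS),
            pd.DataFrame(drug_rows, columns=DRUG_COLUMNS) if drug_rows else _empty(DRUG_COLUMNS),
            pd.DataFrame(reac_rows, columns=REAC_COLUMNS) if reac_rows else _empty(REAC_COLUMNS),
            pd.DataFrame(outc_rows, columns=OUTC_COLUMNS) if outc_rows else _empty(OUTC_COLUMNS),
        )

    def to_reports(self) -> list[CaseReport]:
        drugs_by = {k: g for k, g in self.drugs.groupby("primaryid")} if len(self.drugs) else {}
        reac_by = {k: g for k, g in self.reactions.groupby("primaryid")} if len(self.reactions) else {}
        outc_by = {k: g for k, g in self.outcomes.groupby("primaryid")} if len(self.outcomes) else {}
        out = []
        for row in self.demo.itertuples(index=False):
            pid = row.primaryid
            age = None if row.age in ("", None) else float(row.age)
            out.append(
                CaseReport(
                    case_id=row.caseid,
                    version_stamp=int(row.caseversion),
                    age_value=age,
                    age_unit=row.age_cod or None,
                    sex=row.sex or None,
                    country=row.occr_country or None,
                    drugs=[
                        DrugEntry(t.drugname, t.role_cod)
                        for t in drugs_by.get(pid, _empty(DRUG_COLUMNS)).itertuples(index=False)
                    ],
                    reactions=[t.pt for t in reac_by.get(pid, _empty(REAC_COLUMNS)).itertuples(index=False)],
                    outcomes=[t.outc_cod for t in outc_by.get(pid, _empty(OUTC_COLUMNS)).itertuples(index=False)],
                )
            )
        return out

    # -- basic accessors ----------------------------------------------------

    @property
    def n_versions(self) -> int:
        """Number of report version rows (DEMO rows)."""
        return len(self.demo)

    @property
    def case_ids(self) -> pd.Series:
        return self.demo["caseid"]

    @property
    def n_cases(self) -> int:
        """Number of distinct case identities."""
        return self.demo["caseid"].nunique()

    def subset_primaryids(self, primaryids: Iterable[str]) -> "CaseReportSet":
        keep = set(primaryids)
        return CaseReportSet(
            self.demo[self.demo["primaryid"].isin(keep)].reset_index(drop=True),
            self.drugs[self.drugs["primaryid"].isin(keep)].reset_index(drop=True),
            self.reactions[self.reactions["primaryid"].isin(keep)].reset_index(drop=True),
            self.outcomes[self.outcomes["primaryid"].isin(keep)].reset_index(drop=True),
        )

    def case_pt_pairs(self) -> pd.DataFrame:
        """Distinct (caseid, pt) pairs; the counting unit for disproportionality."""
        if not len(self.reactions):
            return _empty(["caseid", "pt"])
        return self.reactions[["caseid", "pt"]].drop_duplicates().reset_index(drop=True)

    # -- content equality (version stamps excluded) -------------------------

    def content_signature(self) -> frozenset:
        """Canonical content of each case, independent of version stamp and
        primary id. Used for duplicate-injection round-trip checks, where the
        surviving version equals the original content but carries a later stamp."""
        sigs = []
        for r in self.to_reports():
            sigs.append(
                (
                    r.case_id,
                    r.age_value,
                    r.age_unit,
                    r.sex,
                    r.country,
                    frozenset((d.drug_name_verbatim, d.role) for d in r.drugs),
                    frozenset(r.reactions),
                    frozenset(r.outcomes),
                )
            )
        return frozenset(sigs)

    def content_equal(self, other: "CaseReportSet") -> bool:
        return self.content_signature() == other.content_signature()

    # -- file IO -------------------------------------------------------------

    def write_faers(self, directory, compress: bool = False) -> dict:
        """Write DEMO/DRUG/REAC/OUTC as "$"-delimited ASCII files with a
        header row. Returns the mapping table-name -> path."""
        import os

        os.makedirs(directory, exist_ok=True)
        ext = ".txt.gz" if compress else ".txt"
        paths = {}
        for name, df in [
            ("DEMO", self.demo),
            ("DRUG", self.drugs),
            ("REAC", self.reactions),
            ("OUTC", self.outcomes),
        ]:
            path = os.path.join(directory, name + ext)
            df.to_csv(path, sep="$", index=False)
            paths[name] = path
        return paths
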