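"""Reading, deduplicating and filtering spontaneous-report files.

The file dialect is "$"-delimited ASCII with a header row, one file per
table (DEMO, DRUG, REAC, OUTC), plain or gzip-compressed:

    DEMO: primaryid, caseid, caseversion, age, age_cod, sex, occr_country
    DRUG: primaryid, caseid, drugname, role_cod
    REAC: primaryid, caseid, pt
    OUTC: primaryid, caseid, outc_cod

Cases are resubmitted over time; resubmissions share the case id and carry
increasing version stamps. Deduplication keeps the most recent version of
each case. Target-drug retrieval matches verbatim drug names against a
synonym lexicon (generic plus brand names, case-insensitive) and keeps only
reports where the match carries a primary- or secondary-suspect role.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import pandas as pd

from .errors import ParseError, ValidationError
from .types import (
    AgeBand,
    CaseReportSet,
    DEMO_COLUMNS,
    DRUG_COLUMNS,
    OUTC_COLUMNS,
    REAC_COLUMNS,
)

logger = logging.getLogger(__name__)

DELIMITER = "$"


# --- drug-name lexicon -------------------------------------------------------


@dataclass
class DrugLexicon:
    """A canonical drug name plus its synonym set (generic and brand names).

    Matching is case-insensitive on whitespace-trimmed verbatim names; no
    fuzzy matching is attempted.
    """

    canonical_name: str
    synonyms: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.synonyms:
            raise ValidationError("drug lexicon needs at least one synonym")
        self.synonyms = {s.strip().lower() for s in self.synonyms} | {self.canonical_name.strip().lower()}

    def matches(self, verbatim: str) -> bool:
        return verbatim.strip().lower() in self.synonyms

    @classmethod
    def from_tsv(cls, path, canonical_name: str) -> "DrugLexicon":
        """Load from a two-column TSV (canonical, synonym) with a header."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("canonical", "synonym"):
            if col not in df.columns:
                raise ParseError(f"{path}: drug lexicon TSV needs columns 'canonical' and 'synonym'")
        rows = df[df["canonical"].str.strip().str.lower() == canonical_name.strip().lower()]
        return cls(canonical_name=canonical_name, synonyms=set(rows["synonym"].dropna()))


# --- file reading ------------------------------------------------------------


def _read_table(path, expected_columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=DELIMITER, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse '$'-delimited table: {exc}") from exc
    missing = [c for c in expected_columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing mandatory column(s) {missing} in header {list(df.columns)}")
    return df[expected_columns]


def read_faers_tables(demo_path, drug_path, reac_path, outc_path) -> CaseReportSet:
    """Assemble case reports from the four table files.

    One report per DEMO row, joined to DRUG/REAC/OUTC rows on ``primaryid``.
    Reports with no reaction rows (or only blank PT strings) carry no
    analysable event and are dropped with a logged warning, as are reports
    with no drug rows. Dangling DRUG/REAC/OUTC rows referencing no DEMO row
    are dropped with a warning, never fatal.
    """
    demo = _read_table(demo_path, DEMO_COLUMNS)
    drug = _read_table(drug_path, DRUG_COLUMNS)
    reac = _read_table(reac_path, REAC_COLUMNS)
    outc = _read_table(outc_path, OUTC_COLUMNS)

    blank_pt = reac["pt"].str.strip() == ""
    if blank_pt.any():
        logger.warning("%s: dropped %d REAC row(s) with blank PT", reac_path, int(blank_pt.sum()))
        reac = reac[~blank_pt]

    known = set(demo["primaryid"])
    for name, df in (("DRUG", drug), ("REAC", reac), ("OUTC", outc)):
        dangling = ~df["primaryid"].isin(known)
        if dangling.any():
            logger.warning("%d dangling %s row(s) with no matching DEMO row dropped", int(dangling.sum()), name)
    drug = drug[drug["primaryid"].isin(known)]
    reac = reac[reac["primaryid"].isin(known)]
    outc = outc[outc["primaryid"].isin(known)]

    has_reac = demo["primaryid"].isin(set(reac["primaryid"]))
    if (~has_reac).any():
        logger.warning("dropped %d report(s) with no reaction rows", int((~has_reac).sum()))
    has_drug = demo["primaryid"].isin(set(drug["primaryid"]))
    if (has_reac & ~has_drug).any():
        logger.warning("dropped %d report(s) with no drug rows", int((has_reac & ~has_drug).sum()))
    demo = demo[has_reac & has_drug]

    keep = set(demo["primaryid"])
    return CaseReportSet(
        demo.reset_index(drop=True),
        drug[drug["primaryid"].isin(keep)].reset_index(drop=True),
        reac[reac["primaryid"].isin(keep)].reset_index(drop=True),
        outc[outc["primaryid"].isin(keep)].reset_index(drop=True),
    )


# --- deduplication -----------------------------------------------------------


def deduplicate_cases(cases: CaseReportSet) -> CaseReportSet:
    """Keep the most recent version of each case id.

    "Most recent" is the maximum version stamp (numeric when all stamps
    parse as numbers, else lexicographic). Tied stamps keep the row with the
    lexicographically greatest primary id; every tie is logged. Idempotent:
    output has exactly one row per distinct case id.
    """
    demo = cases.demo
    if not len(demo):
        return cases
    version_num = pd.to_numeric(demo["caseversion"], errors="coerce")
    sort_key = version_num if not version_num.isna().any() else demo["caseversion"]
    ordered = demo.assign(_v=sort_key).sort_values(
        ["caseid", "_v", "primaryid"], kind="mergesort"
    )
    ties = ordered.duplicated(subset=["caseid", "_v"], keep=False)
    if ties.any():
        for cid in ordered.loc[ties, "caseid"].unique():
            logger.warning("case %s has tied version stamps; keeping greatest primaryid", cid)
    keep = ordered.drop_duplicates(subset="caseid", keep="last")["primaryid"]
    return cases.subset_primaryids(keep)


# --- target-drug filter ------------------------------------------------------


def filter_target_drug(
    cases: CaseReportSet,
    lexicon: DrugLexicon,
    allowed_roles: Iterable[str] = ("PS", "SS"),
    return_matches: bool = False,
):
    """Retain cases with >=1 drug row matching the lexicon in an allowed role.

    With ``return_matches=True`` additionally returns the matching drug rows
    (per retained case: the verbatim name and role that triggered retention).
    """
    roles = set(allowed_roles)
    drug = cases.drugs
    if len(drug):
        name_match = drug["drugname"].str.strip().str.lower().isin(lexicon.synonyms)
        hit = drug[name_match & drug["role_cod"].isin(roles)]
    else:
        hit = drug
    keep_ids = set(hit["primaryid"])
    filtered = cases.subset_primaryids(keep_ids)
    if return_matches:
        return filtered, hit.reset_index(drop=True)
    return filtered


# --- age banding -------------------------------------------------------------

_AGE_UNIT_YEARS = {"YR": 1.0, "MON": 1 / 12, "DY": 1 / 365.25}


def assign_age_band(age_value: Optional[float], age_unit: Optional[str]) -> AgeBand:
    """Band an age into <19 y, 19-64 y, >=65 y, or UNKNOWN.

    Units YR/MON/DY are converted to years before banding; missing values
    and unrecognised unit codes yield UNKNOWN (the latter with a warning).
    """
    if age_value is None or (isinstance(age_value, float) and pd.isna(age_value)):
        return AgeBand.UNKNOWN
    if age_value < 0:
        raise ValidationError(f"negative age {age_value!r}")
    unit = (age_unit or "YR").strip().upper()
    if unit not in _AGE_UNIT_YEARS:
        logger.warning("unknown age unit code %r; age treated as unknown", age_unit)
        return AgeBand.UNKNOWN
    years = age_value * _AGE_UNIT_YEARS[unit]
    if years < 19:
        return AgeBand.CHILD_ADOLESCENT
    if years < 65:
        return AgeBand.ADULT
    return AgeBand.OLDER_ADULT


def assign_age_bands(demo: pd.DataFrame) -> pd.Series:
    """Vectorised banding over a DEMO table (string age/age_cod columns)."""
    age = pd.to_numeric(demo["age"].replace("", None), errors="coerce")
    if (age < 0).any():
        raise ValidationError("negative age value(s) in DEMO table")
    factors = demo["age_cod"].str.strip().str.upper().map(_AGE_UNIT_YEARS)
    years = age * factors.fillna(float("nan"))
    bands = pd.Series(AgeBand.UNKNOWN.value, index=demo.index, dtype=object)
    bands[years < 19] = AgeBand.CHILD_ADOLESCENT.value
    bands[(years >= 19) & (years < 65)] = AgeBand.ADULT.value
    bands[years >= 65] = AgeBand.OLDER_ADULT.value
    return bands
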