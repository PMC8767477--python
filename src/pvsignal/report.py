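"""Descriptive output tables: demographics, PT/SOC frequencies, comparisons.

Every table carries its denominator explicitly: demographic tables are
percentages of *patients*, PT and SOC frequency tables are percentages of
*adverse events* (distinct patient-PT pairs). Percentages display half-up
rounded to 2 decimal places, means and ratios to 1; full precision is kept
internally. Report generation is pure — the same inputs always produce the
same tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import pandas as pd

from .ingest import assign_age_bands
from .types import AgeBand, CaseReportSet


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (5 rounds away from zero), as tables print it."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class FrequencyTable:
    """Rows of (label, count, percent) over an explicit denominator."""

    rows: pd.DataFrame  # columns: label, count, percent
    total: int
    source: str  # e.g. "reports" or "reviews"
    denominator: str  # e.g. "patients" or "adverse events"

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def frequency_from_counts(
    counts: Sequence[tuple[str, int]],
    total: Optional[int] = None,
    source: str = "reports",
    denominator: str = "patients",
) -> FrequencyTable:
    """Build a frequency table from (label, count) pairs.

    ``total`` defaults to the sum of counts; give it explicitly when the
    denominator is larger than the listed rows (e.g. a top-n excerpt).
    """
    tot = int(total) if total is not None else int(sum(c for _, c in counts))
    rows = pd.DataFrame(
        {
            "label": [label for label, _ in counts],
            "count": [int(c) for _, c in counts],
        }
    )
    rows["percent"] = [round_half_up(100.0 * c / tot, 2) if tot else float("nan") for c in rows["count"]]
    return FrequencyTable(rows=rows, total=tot, source=source, denominator=denominator)


# --- patient-level demographic tables ---------------------------------------

_AGE_LABELS = {
    AgeBand.CHILD_ADOLESCENT.value: "Less than 19 years old",
    AgeBand.ADULT.value: "19-64 years old",
    AgeBand.OLDER_ADULT.value: "More than 64 years old",
    AgeBand.UNKNOWN.value: "Unknown",
}
_SEX_LABELS = {"F": "Women", "M": "Men", "": "Unknown"}


def patients_from_cases(cases: CaseReportSet) -> pd.DataFrame:
    """One row per deduplicated patient: age_band, sex, country."""
    demo = cases.demo
    out = pd.DataFrame(
        {
            "patient_id": demo["caseid"].to_numpy(object),
            "age_band": assign_age_bands(demo).to_numpy(object),
            "sex": demo["sex"].map(lambda s: s if s in ("F", "M") else "").to_numpy(object),
            "country": demo["occr_country"].to_numpy(object),
        }
    )
    return out


def patients_from_posts(posts: pd.DataFrame) -> pd.DataFrame:
    """One row per review post, with the raw age band mapped onto the
    <19 / 19-64 / >=65 partition (review sites band ages coarsely; bands
    spanning 65, e.g. none of the defaults, would raise)."""

    def band(raw: str) -> str:
        if not raw:
            return AgeBand.UNKNOWN.value
        if raw.endswith("or over"):
            low = int(raw.split()[0])
            return AgeBand.OLDER_ADULT.value if low >= 65 else AgeBand.ADULT.value
        lo, _, hi = raw.partition("-")
        lo_v, hi_v = int(lo), int(hi)
        if hi_v < 19:
            return AgeBand.CHILD_ADOLESCENT.value
        if hi_v < 65:
            return AgeBand.ADULT.value
        if lo_v >= 65:
            return AgeBand.OLDER_ADULT.value
        raise ValueError(f"age band {raw!r} straddles the 65-year boundary")

    return pd.DataFrame(
        {
            "patient_id": posts["post_id"].to_numpy(object),
            "age_band": [band(str(b)) for b in posts["age_band"]],
            "sex": posts["sex"].map(lambda s: s if s in ("F", "M") else "").to_numpy(object),
            "country": "",
        }
    )


def demographics_table(patients: pd.DataFrame, source: str = "reports") -> dict[str, FrequencyTable]:
    """Age-band, sex, and country frequency tables over the patient total.

    The Unknown row is always present for age and sex, even at count 0.
    """
    total = len(patients)
    tables: dict[str, FrequencyTable] = {}

    age_counts = patients["age_band"].value_counts()
    age_rows = [
        (_AGE_LABELS[band], int(age_counts.get(band, 0)))
        for band in (
            AgeBand.CHILD_ADOLESCENT.value,
            AgeBand.ADULT.value,
            AgeBand.OLDER_ADULT.value,
            AgeBand.UNKNOWN.value,
        )
    ]
    tables["age"] = frequency_from_counts(age_rows, total=total, source=source, denominator="patients")

    sex_counts = patients["sex"].value_counts()
    sex_rows = [(_SEX_LABELS[code], int(sex_counts.get(code, 0))) for code in ("F", "M", "")]
    tables["sex"] = frequency_from_counts(sex_rows, total=total, source=source, denominator="patients")

    country = patients["country"].map(lambda c: c if c else "Unknown")
    country_counts = country.value_counts()
    known = sorted(c for c in country_counts.index if c != "Unknown")
    country_rows = [(c, int(country_counts[c])) for c in known]
    country_rows.append(("Unknown", int(country_counts.get("Unknown", 0))))
    tables["country"] = frequency_from_counts(country_rows, total=total, source=source, denominator="patients")
    return tables


# --- AE-level frequency tables ----------------------------------------------


def pt_frequency_table(
    occurrences: pd.DataFrame,
    n_patients: Optional[int] = None,
    source: str = "reports",
) -> tuple[FrequencyTable, float]:
    """PT frequency table plus the mean PTs per patient.

    ``occurrences`` has one row per (patient_id, pt); duplicates collapse
    (two listings of one PT in one patient are one AE, two distinct PTs are
    two AEs). Percentages are of total AEs; the mean is total AEs divided by
    the patient total (``n_patients`` defaults to the distinct patients
    observed). Zero patients yield an empty table and a NaN mean.
    """
    occ = occurrences[["patient_id", "pt"]].drop_duplicates()
    n_pat = int(n_patients) if n_patients is not None else occ["patient_id"].nunique()
    if n_pat == 0:
        empty = frequency_from_counts([], total=0, source=source, denominator="adverse events")
        return empty, float("nan")
    counts = occ["pt"].value_counts()
    rows = [(pt, int(c)) for pt, c in counts.sort_values(ascending=False).items()]
    table = frequency_from_counts(rows, source=source, denominator="adverse events")
    mean = table.total / n_pat
    return table, mean


def mean_pts_display(mean: float) -> str:
    """The mean as displayed (1 decimal place, half-up); NaN prints as NA."""
    return "NA" if pd.isna(mean) else format(round_half_up(mean, 1), ".1f")


# --- cross-source comparison -------------------------------------------------


def compare_sources(table_a: FrequencyTable, table_b: FrequencyTable) -> pd.DataFrame:
    """Side-by-side rows aligned on label; a label present in only one
    source shows blank cells (not zeros) for the other."""
    a = table_a.rows.rename(
        columns={"count": f"count_{table_a.source}", "percent": f"percent_{table_a.source}"}
    )
    b = table_b.rows.rename(
        columns={"count": f"count_{table_b.source}", "percent": f"percent_{table_b.source}"}
    )
    merged = a.merge(b, on="label", how="outer")
    order = list(dict.fromkeys(list(a["label"]) + list(b["label"])))
    merged = merged.set_index("label").loc[order].reset_index()
    return merged.astype(object).where(merged.notna(), "")
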