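"""Signal classification: new vs labelled, serious flags, SOC rollups.

A detected signal is *new* when its PT is absent from the drug's label term
set. A signal PT is *serious* when the share of its supporting cases
carrying a serious outcome code (death, life-threat, hospitalization,
disability by default) exceeds a threshold (default 0: any serious case
suffices), or the PT is on an always-serious override list. PT-level counts
roll up to system organ classes through a user-supplied PT -> SOC map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .errors import ParseError
from .types import CaseReportSet, SERIOUS_OUTCOME_CODES

logger = logging.getLogger(__name__)


@dataclass
class LabelPTSet:
    """PTs already described on a drug's label, with a source note per PT."""

    drug: str
    labelled_pts: set
    source: dict = field(default_factory=dict)  # pt -> provenance note

    @classmethod
    def from_tsv(cls, path, drug: str) -> "LabelPTSet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if "pt" not in df.columns:
            raise ParseError(f"{path}: label TSV needs a 'pt' column")
        notes = dict(zip(df["pt"], df["source"])) if "source" in df.columns else {}
        return cls(drug=drug, labelled_pts=set(df["pt"].dropna()), source=notes)


@dataclass
class MedDRAMap:
    """Total map PT -> primary SOC over the vocabulary in use."""

    mapping: dict

    @classmethod
    def from_tsv(cls, path) -> "MedDRAMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("pt", "soc"):
            if col not in df.columns:
                raise ParseError(f"{path}: PT->SOC TSV needs columns 'pt' and 'soc'")
        return cls(mapping=dict(zip(df["pt"], df["soc"])))

    def soc_of(self, pt: str) -> Optional[str]:
        return self.mapping.get(pt)


@dataclass
class SeriousnessRule:
    """Which outcome codes count as serious and how many supporting cases
    must carry one (strict proportion threshold; 0 means any)."""

    serious_outcome_codes: frozenset = frozenset(SERIOUS_OUTCOME_CODES)
    proportion_threshold: float = 0.0
    pt_override_list: frozenset = frozenset()


def flag_new_signals(
    signals: pd.DataFrame,
    label_set: LabelPTSet,
    vocabulary: Optional[Iterable[str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Partition signal rows into (new, labelled) by label membership.

    PTs absent from ``vocabulary`` (when given) go to a review list instead
    of being classified. The partition of classified rows is exhaustive and
    disjoint.
    """
    df = signals.copy()
    review: list[str] = []
    if vocabulary is not None:
        vocab = set(vocabulary)
        unknown = ~df["pt"].isin(vocab)
        review = sorted(df.loc[unknown, "pt"])
        if review:
            logger.warning("%d signal PT(s) outside the vocabulary routed to review: %s", len(review), review)
        df = df[~unknown]
    is_new = ~df["pt"].isin(label_set.labelled_pts)
    return df[is_new].reset_index(drop=True), df[~is_new].reset_index(drop=True), review


def flag_serious(
    cases: CaseReportSet,
    signals: pd.DataFrame,
    rule: SeriousnessRule = SeriousnessRule(),
) -> pd.DataFrame:
    """Add is_serious / serious_case_fraction / serious_reason columns.

    The supporting cases of a signal PT are the deduplicated target cases
    listing that PT; the fraction of them with >=1 serious outcome code is
    compared with the rule's threshold. With no outcome data at all, flags
    are unknown (NA) with a warning.
    """
    out = signals.copy()
    if not len(cases.outcomes):
        logger.warning("no outcome rows available; serious flags are unknown")
        out["serious_case_fraction"] = float("nan")
        out["is_serious"] = pd.NA
        out["serious_reason"] = "no outcome data"
        return out

    serious_ids = set(
        cases.outcomes.loc[cases.outcomes["outc_cod"].isin(rule.serious_outcome_codes), "caseid"]
    )
    pairs = cases.case_pt_pairs()
    fractions, flags, reasons = [], [], []
    for pt in out["pt"]:
        ids = set(pairs.loc[pairs["pt"] == pt, "caseid"])
        frac = len(ids & serious_ids) / len(ids) if ids else 0.0
        override = pt in rule.pt_override_list
        flag = override or frac > rule.proportion_threshold
        fractions.append(frac)
        flags.append(flag)
        if override:
            reasons.append("override list")
        elif flag:
            reasons.append(f"serious outcome in {frac:.0%} of cases")
        else:
            reasons.append("")
    out["serious_case_fraction"] = fractions
    out["is_serious"] = flags
    out["serious_reason"] = reasons
    return out


def rollup_soc(
    pt_table: pd.DataFrame,
    meddra: MedDRAMap,
    top_n: Optional[int] = None,
) -> pd.DataFrame:
    """Aggregate a (pt, count) table to SOC counts with percentages of the
    AE total (2 decimal places). Unmapped PTs fall into an "Others" bucket
    with a warning. With ``top_n``, rows beyond the top n merge into
    "Others" so the table mirrors a top-n presentation."""
    from .report import round_half_up

    df = pt_table.copy()
    soc = df["pt"].map(meddra.mapping)
    unmapped = soc.isna()
    if unmapped.any():
        logger.warning("%d PT(s) missing from the PT->SOC map counted under 'Others'", int(unmapped.sum()))
    df["soc"] = soc.fillna("Others")
    agg = df.groupby("soc", as_index=False)["count"].sum().sort_values(["count", "soc"], ascending=[False, True])
    total = int(agg["count"].sum())
    if top_n is not None:
        named = agg[agg["soc"] != "Others"]
        head = named.head(top_n)
        others_count = total - int(head["count"].sum())
        if others_count > 0 or "Others" in agg["soc"].values or len(named) > top_n:
            agg = pd.concat([head, pd.DataFrame([{"soc": "Others", "count": others_count}])], ignore_index=True)
        else:
            agg = head
    agg = agg.reset_index(drop=True)
    agg["percent"] = [round_half_up(100.0 * c / total, 2) if total else float("nan") for c in agg["count"]]
    return agg
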