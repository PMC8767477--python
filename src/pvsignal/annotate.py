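"""Review-post filtering, phrase-to-PT mapping, and two-annotator adjudication.

Patient drug-review posts are filtered (rating-only posts and posts flagged
as unrelated to adverse events are excluded) and their free text is mapped
to MedDRA preferred terms through a surface-phrase lexicon. The mapper is a
transparent stand-in for human coding: a case-insensitive, longest-phrase-
first, non-overlapping scan. Negation is not handled ("no nausea" still
maps to Nausea) — a documented limitation.

Two annotations of the same post are adjudicated set-wise: the intersection
is auto-accepted, the symmetric difference becomes a disagreement queue that
must be resolved through an explicit resolution table (post_id, pt,
decision, note); nothing is dropped silently.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

POST_COLUMNS = ["post_id", "drug_label", "age_band", "sex", "duration_band", "text", "rating_only", "non_ae_flag"]


@dataclass
class SymptomLexicon:
    """Many-to-one mapping from lowercase surface phrases to PTs."""

    entries: dict[str, str]
    _pattern: re.Pattern = field(init=False, repr=False)

    def __post_init__(self) -> None:
        cleaned = {}
        for phrase, pt in self.entries.items():
            phrase = phrase.strip().lower()
            if not phrase:
                raise ValidationError("lexicon phrases must be non-empty")
            cleaned[phrase] = pt
        if not cleaned:
            raise ValidationError("symptom lexicon is empty")
        self.entries = cleaned
        ordered = sorted(cleaned, key=len, reverse=True)  # longest-phrase-first
        self._pattern = re.compile(r"\b(?:" + "|".join(re.escape(p) for p in ordered) + r")\b")

    @property
    def pts(self) -> set[str]:
        return set(self.entries.values())

    @classmethod
    def from_tsv(cls, path, soc_map: Optional[Mapping[str, str]] = None) -> "SymptomLexicon":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("phrase", "pt"):
            if col not in df.columns:
                raise ParseError(f"{path}: lexicon TSV needs columns 'phrase' and 'pt'")
        lex = cls(dict(zip(df["phrase"], df["pt"])))
        if soc_map is not None:
            unmapped = lex.pts - set(soc_map)
            if unmapped:
                raise ValidationError(f"lexicon PTs missing from the PT->SOC map: {sorted(unmapped)}")
        return lex


@dataclass(frozen=True)
class PTAnnotation:
    """The PT set one annotator assigned to one post."""

    post_id: str
    annotator_id: str
    pts: frozenset


def read_posts_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"post_id": str}, keep_default_na=False)
    missing = [c for c in POST_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: review CSV missing column(s) {missing}")
    for flag in ("rating_only", "non_ae_flag"):
        df[flag] = df[flag].astype(str).str.lower().isin({"true", "1", "yes"}) if df[flag].dtype == object else df[flag]
    return df


def filter_posts(posts: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop rating-only posts and posts flagged as not AE-related.

    Returns the retained posts and the per-reason exclusion counts, which
    are also logged.
    """
    rating_only = posts["rating_only"].astype(bool)
    non_ae = posts["non_ae_flag"].astype(bool) & ~rating_only
    kept = posts[~rating_only & ~posts["non_ae_flag"].astype(bool)].reset_index(drop=True)
    reasons = {"rating_only": int(rating_only.sum()), "non_ae": int(non_ae.sum())}
    logger.info("post filtering: kept %d, excluded %s", len(kept), reasons)
    return kept, reasons


def map_text_to_pts(text: str, lexicon: SymptomLexicon) -> set[str]:
    """Scan text for lexicon phrases; matched phrases contribute their PTs.

    Case-insensitive; whitespace runs collapse; matches are longest-first
    and non-overlapping left to right; the result is a set.
    """
    if not text:
        return set()
    normalised = re.sub(r"\s+", " ", text.lower())
    return {lexicon.entries[m.group(0)] for m in lexicon._pattern.finditer(normalised)}


def annotate_posts(posts: pd.DataFrame, lexicon: SymptomLexicon, annotator_id: str = "lexicon") -> list[PTAnnotation]:
    """Annotate every post with the lexicon mapper."""
    return [
        PTAnnotation(post_id=row.post_id, annotator_id=annotator_id, pts=frozenset(map_text_to_pts(row.text, lexicon)))
        for row in posts.itertuples(index=False)
    ]


@dataclass
class Adjudication:
    """Outcome of comparing two annotations of one post."""

    post_id: str
    final_pts: set
    disagreements: set  # PTs assigned by exactly one annotator, pending resolution


def adjudicate(a1: PTAnnotation, a2: PTAnnotation) -> Adjudication:
    """Intersection auto-accepted; symmetric difference queued for resolution."""
    if a1.post_id != a2.post_id:
        raise ValidationError(f"annotations refer to different posts: {a1.post_id!r} vs {a2.post_id!r}")
    return Adjudication(
        post_id=a1.post_id,
        final_pts=set(a1.pts & a2.pts),
        disagreements=set(a1.pts ^ a2.pts),
    )


def read_resolutions_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("post_id", "pt", "decision"):
        if col not in df.columns:
            raise ParseError(f"{path}: resolution CSV needs columns post_id, pt, decision")
    bad = ~df["decision"].str.lower().isin({"accept", "reject"})
    if bad.any():
        raise ParseError(f"{path}: decisions must be 'accept' or 'reject'")
    return df


def apply_resolutions(adjudication: Adjudication, resolutions: pd.DataFrame) -> set:
    """Resolve every queued disagreement from the resolution table.

    Accepted PTs join the final set; rejected PTs are dropped. A queued PT
    with no resolution row is an error — disagreements are never silently
    discarded.
    """
    rel = resolutions[resolutions["post_id"] == adjudication.post_id]
    decided = dict(zip(rel["pt"], rel["decision"].str.lower()))
    unresolved = adjudication.disagreements - set(decided)
    if unresolved:
        raise ValidationError(
            f"post {adjudication.post_id}: unresolved disagreement PTs {sorted(unresolved)}"
        )
    final = set(adjudication.final_pts)
    for pt in adjudication.disagreements:
        if decided[pt] == "accept":
            final.add(pt)
    return final


def final_annotation_table(
    posts: pd.DataFrame,
    lexicon: SymptomLexicon,
    resolutions: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Single-pass convenience: filter posts, annotate with the lexicon, and
    return one row per (post_id, pt). With a resolution table, a second
    'reviewer' column could disagree; with the deterministic mapper both
    annotators agree, so the queue is empty unless resolutions add PTs."""
    kept, _ = filter_posts(posts)
    rows = []
    for ann in annotate_posts(kept, lexicon):
        pts = set(ann.pts)
        if resolutions is not None:
            rel = resolutions[resolutions["post_id"] == ann.post_id]
            for pt, decision in zip(rel["pt"], rel["decision"].str.lower()):
                if decision == "accept":
                    pts.add(pt)
                else:
                    pts.discard(pt)
        for pt in sorted(pts):
            rows.append({"post_id": ann.post_id, "pt": pt})
    return pd.DataFrame(rows, columns=["post_id", "pt"])
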