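"""Synthetic spontaneous reports and review posts with planted signals.

The generator emulates the statistical structure a disproportionality
analysis assumes: case reports carrying one or more reaction PTs, drug rows
with suspect-role codes, resubmitted duplicate versions, per-field missing
demographics — plus a configurable set of planted drug-event associations
whose strength is known, so recovery can be tested.

Event mechanism
---------------
Each case draws a baseline PT count ``m`` from ``pts_per_case_dist`` and then
``m`` i.i.d. categorical draws over the *non-planted* vocabulary (weights
renormalised), keeping distinct terms; this guarantees every case at least
one PT and is identical for target-drug and comparator cases. Each planted
PT is simulated separately as an independent per-case Bernoulli presence:
probability ``p`` (its stated background probability) for comparator cases
and ``min(1, rho * p)`` for target-drug cases. The per-case probability of a
planted event given the target drug is therefore *exactly* ``rho`` times its
background probability, so ``rho`` equals the asymptotic proportional
reporting ratio and recovery tests are directly interpretable.

Duplicate versions
------------------
A selected case gains one or two extra versions with strictly later stamps;
intermediate versions carry perturbed demographics while the latest is an
exact content copy of the original, so deduplication (keep most recent)
restores the pre-injection case content exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from . import resources
from .errors import ConfigurationError
from .types import CaseReportSet, DEMO_COLUMNS, DRUG_COLUMNS, OUTC_COLUMNS, REAC_COLUMNS

_COUNTRIES = ["US", "DE", "GB", "FR", "CA", "JP", "AU", "BR"]
_COUNTRY_P = [0.45, 0.12, 0.10, 0.08, 0.07, 0.06, 0.06, 0.06]

_AGE_BANDS_RAW = ["13-18", "19-24", "25-34", "35-44", "45-54", "55-64", "65-74", "75 or over"]
_AGE_BAND_P = [0.02, 0.07, 0.16, 0.22, 0.24, 0.16, 0.09, 0.04]
_DURATION_BANDS = [
    "less than 1 month",
    "1-6 months",
    "6 months to less than 1 year",
    "1 to less than 2 years",
    "2 to less than 5 years",
    "5 to less than 10 years",
    "10 years or more",
]


def _probability(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name}={value!r} is not a probability in [0, 1]")


class SimConfig(BaseModel):
    """Generator configuration; defaults are the package's study conditions.

    ``event_vocabulary`` maps PT -> background probability (per categorical
    draw for baseline terms, per case for planted terms); ``planted_signals``
    maps PT -> relative reporting rate rho (rho = 1 is an explicit null
    pair). ``pts_per_case_dist`` maps PT count -> probability.
    """

    n_cases: int = Field(default=20_000, ge=0)
    target_drug: str = "tramadol"
    background_drugs: list[str] = Field(default_factory=lambda: list(resources.DEFAULT_BACKGROUND_DRUGS))
    event_vocabulary: dict[str, float] = Field(default_factory=lambda: dict(resources.DEFAULT_EVENT_VOCABULARY))
    planted_signals: dict[str, float] = Field(default_factory=dict)
    pts_per_case_dist: dict[int, float] = Field(
        default_factory=lambda: {1: 0.20, 2: 0.20, 3: 0.20, 4: 0.15, 5: 0.13, 6: 0.12}
    )
    suspect_role_probs: dict[str, float] = Field(
        default_factory=lambda: {"PS": 0.70, "SS": 0.18, "C": 0.09, "I": 0.03}
    )
    target_drug_prevalence: float = 0.10
    comedication_prob: float = 0.50
    duplicate_rate: float = 0.05
    demographic_missingness: dict[str, float] = Field(
        default_factory=lambda: {"age": 0.25, "sex": 0.10, "country": 0.05}
    )
    outcome_probs: dict[str, float] = Field(
        default_factory=lambda: {"OT": 0.25, "HO": 0.08, "DE": 0.02, "LT": 0.01, "DS": 0.01, "CA": 0.002, "RI": 0.005}
    )
    n_posts: int = Field(default=2062, ge=0)
    rating_only_rate: float = 0.40
    non_ae_rate: float = 0.07
    seed: int = 0

    @field_validator("event_vocabulary")
    @classmethod
    def _check_vocab(cls, v: dict[str, float]) -> dict[str, float]:
        for pt, p in v.items():
            _probability(f"event_vocabulary[{pt!r}]", p)
        if sum(v.values()) > 1.0 + 1e-9:
            raise ConfigurationError("event vocabulary probabilities must sum to <= 1 per draw")
        return v

    @field_validator("planted_signals")
    @classmethod
    def _check_planted(cls, v: dict[str, float]) -> dict[str, float]:
        for pt, rho in v.items():
            if rho < 0:
                raise ConfigurationError(f"planted rho for {pt!r} must be >= 0")
        return v

    @field_validator("pts_per_case_dist")
    @classmethod
    def _check_dist(cls, v: dict[int, float]) -> dict[int, float]:
        if not v:
            raise ConfigurationError("pts_per_case_dist must be non-empty")
        for k, p in v.items():
            if k < 1:
                raise ConfigurationError("PT counts per case must be >= 1")
            _probability(f"pts_per_case_dist[{k}]", p)
        total = sum(v.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigurationError("pts_per_case_dist probabilities must sum to 1")
        return v

    @field_validator("suspect_role_probs")
    @classmethod
    def _check_roles(cls, v: dict[str, float]) -> dict[str, float]:
        if not set(v) <= {"PS", "SS", "C", "I"}:
            raise ConfigurationError("suspect role codes must be among PS, SS, C, I")
        for role, p in v.items():
            _probability(f"suspect_role_probs[{role}]", p)
        if abs(sum(v.values()) - 1.0) > 1e-6:
            raise ConfigurationError("suspect role probabilities must sum to 1")
        return v

    @field_validator(
        "target_drug_prevalence", "comedication_prob", "duplicate_rate", "rating_only_rate", "non_ae_rate"
    )
    @classmethod
    def _check_prob_fields(cls, v: float) -> float:
        _probability("probability field", v)
        return v

    @field_validator("demographic_missingness", "outcome_probs")
    @classmethod
    def _check_prob_maps(cls, v: dict[str, float]) -> dict[str, float]:
        for k, p in v.items():
            _probability(k, p)
        return v

    @model_validator(mode="after")
    def _check_consistency(self) -> "SimConfig":
        if not set(self.planted_signals) <= set(self.event_vocabulary):
            raise ConfigurationError("planted PTs must appear in the event vocabulary")
        if self.n_cases > 0:
            if not self.event_vocabulary:
                raise ConfigurationError("event vocabulary is empty but n_cases > 0")
            if not (set(self.event_vocabulary) - set(self.planted_signals)):
                raise ConfigurationError(
                    "at least one non-planted vocabulary PT is needed to guarantee every case a baseline event"
                )
            if not self.background_drugs:
                raise ConfigurationError("background drug list is empty")
        return self

    def baseline_pts(self) -> list[str]:
        return [pt for pt in self.event_vocabulary if pt not in self.planted_signals]


@dataclass
class SignalTruth:
    """Ground truth emitted alongside a simulation.

    ``pairs`` are planted associations (drug, PT, rho != 1); ``null_pairs``
    are pairs known to have no effect (explicit rho = 1 plants plus every
    baseline vocabulary PT).
    """

    pairs: list[tuple[str, str, float]] = field(default_factory=list)
    null_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"pairs": self.pairs, "null_pairs": self.null_pairs}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SignalTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            pairs=[tuple(p) for p in d["pairs"]],
            null_pairs=[tuple(p) for p in d["null_pairs"]],
        )


def _truth_for(config: SimConfig) -> SignalTruth:
    pairs = [(config.target_drug, pt, rho) for pt, rho in config.planted_signals.items() if rho != 1.0]
    nulls = [(config.target_drug, pt) for pt, rho in config.planted_signals.items() if rho == 1.0]
    nulls += [(config.target_drug, pt) for pt in config.baseline_pts()]
    return SignalTruth(pairs=pairs, null_pairs=nulls)


def simulate_reports(config: SimConfig) -> tuple[CaseReportSet, SignalTruth]:
    """Generate case reports (with duplicate versions per
    ``config.duplicate_rate``) and the planted ground truth.

    Reproducible: identical configs (including seed) give identical output.
    """
    truth = _truth_for(config)
    n = config.n_cases
    if n == 0:
        return CaseReportSet.empty(), truth

    rng = np.random.default_rng(config.seed)
    caseids = np.array([str(10_000_000 + i) for i in range(n)], dtype=object)
    versions = np.ones(n, dtype=int)
    primaryids = np.array([f"{cid}{v:02d}" for cid, v in zip(caseids, versions)], dtype=object)
    target_mask = rng.random(n) < config.target_drug_prevalence

    # --- reactions: baseline categorical layer -----------------------------
    baseline = config.baseline_pts()
    weights = np.array([config.event_vocabulary[pt] for pt in baseline], float)
    weights = weights / weights.sum()
    counts = np.array(sorted(config.pts_per_case_dist))
    count_p = np.array([config.pts_per_case_dist[k] for k in counts], float)
    m = rng.choice(counts, size=n, p=count_p / count_p.sum())
    flat_pt = rng.choice(len(baseline), size=int(m.sum()), p=weights)
    flat_case = np.repeat(np.arange(n), m)
    reac = pd.DataFrame({"case_idx": flat_case, "pt": np.array(baseline, object)[flat_pt]})
    reac = reac.drop_duplicates()

    # --- reactions: planted Bernoulli layer --------------------------------
    planted_frames = []
    for pt, rho in config.planted_signals.items():
        p_bg = config.event_vocabulary[pt]
        p_target = min(1.0, rho * p_bg)
        u = rng.random(n)
        present = np.where(target_mask, u < p_target, u < p_bg)
        idx = np.nonzero(present)[0]
        planted_frames.append(pd.DataFrame({"case_idx": idx, "pt": pt}))
    if planted_frames:
        reac = pd.concat([reac] + planted_frames, ignore_index=True)
    reac = reac.sort_values(["case_idx", "pt"]).reset_index(drop=True)
    reactions = pd.DataFrame(
        {
            "primaryid": primaryids[reac["case_idx"].to_numpy()],
            "caseid": caseids[reac["case_idx"].to_numpy()],
            "pt": reac["pt"].to_numpy(object),
        }
    )

    # --- drugs --------------------------------------------------------------
    roles = list(config.suspect_role_probs)
    role_p = np.array([config.suspect_role_probs[r] for r in roles], float)
    target_idx = np.nonzero(target_mask)[0]
    bg_idx = np.nonzero(~target_mask)[0]
    target_roles = rng.choice(roles, size=len(target_idx), p=role_p / role_p.sum())
    bg_choice_t = rng.choice(config.background_drugs, size=len(target_idx))
    comed = rng.random(len(target_idx)) < config.comedication_prob
    bg_choice_b = rng.choice(config.background_drugs, size=len(bg_idx))

    drug_frames = [
        pd.DataFrame(
            {
                "case_idx": target_idx,
                "drugname": config.target_drug,
                "role_cod": target_roles,
            }
        ),
        pd.DataFrame(
            {
                "case_idx": target_idx[comed],
                "drugname": bg_choice_t[comed],
                "role_cod": "C",
            }
        ),
        pd.DataFrame({"case_idx": bg_idx, "drugname": bg_choice_b, "role_cod": "PS"}),
    ]
    drug = pd.concat(drug_frames, ignore_index=True).sort_values(["case_idx", "role_cod"]).reset_index(drop=True)
    drugs = pd.DataFrame(
        {
            "primaryid": primaryids[drug["case_idx"].to_numpy()],
            "caseid": caseids[drug["case_idx"].to_numpy()],
            "drugname": drug["drugname"].to_numpy(object),
            "role_cod": drug["role_cod"].to_numpy(object),
        }
    )

    # --- demographics -------------------------------------------------------
    age = np.clip(np.round(rng.normal(50.0, 17.0, size=n)), 1, 95).astype(int)
    sex = rng.choice(["F", "M"], size=n, p=[0.55, 0.45])
    country = rng.choice(_COUNTRIES, size=n, p=_COUNTRY_P)
    age_str = age.astype(str).astype(object)
    age_cod = np.full(n, "YR", dtype=object)
    miss = config.demographic_missingness
    if miss.get("age", 0) > 0:
        blank = rng.random(n) < miss["age"]
        age_str[blank] = ""
        age_cod[blank] = ""
    sex = sex.astype(object)
    if miss.get("sex", 0) > 0:
        sex[rng.random(n) < miss["sex"]] = ""
    country = country.astype(object)
    if miss.get("country", 0) > 0:
        country[rng.random(n) < miss["country"]] = ""
    demo = pd.DataFrame(
        {
            "primaryid": primaryids,
            "caseid": caseids,
            "caseversion": versions.astype(str).astype(object),
            "age": age_str,
            "age_cod": age_cod,
            "sex": sex,
            "occr_country": country,
        }
    )

    # --- outcomes -----------------------------------------------------------
    outc_frames = []
    for code, p in config.outcome_probs.items():
        hit = np.nonzero(rng.random(n) < p)[0]
        if len(hit):
            outc_frames.append(
                pd.DataFrame({"primaryid": primaryids[hit], "caseid": caseids[hit], "outc_cod": code})
            )
    outcomes = (
        pd.concat(outc_frames, ignore_index=True).sort_values(["caseid", "outc_cod"]).reset_index(drop=True)
        if outc_frames
        else pd.DataFrame({c: pd.Series(dtype=object) for c in OUTC_COLUMNS})
    )

    cases = CaseReportSet(demo, drugs, reactions, outcomes)
    if config.duplicate_rate > 0:
        cases = inject_duplicates(cases, config.duplicate_rate, seed=config.seed + 1)
    return cases, truth


def inject_duplicates(cases: CaseReportSet, duplicate_rate: float, seed: int) -> CaseReportSet:
    """Give selected cases extra later-stamped versions.

    Each selected case gains 1-2 additional versions; intermediate versions
    have jittered age, the latest is an exact content copy, so keep-most-
    recent deduplication restores the pre-injection content exactly.
    """
    _probability("duplicate_rate", duplicate_rate)
    if duplicate_rate == 0 or not len(cases.demo):
        return cases
    rng = np.random.default_rng(seed)

    demo = cases.demo
    version_num = pd.to_numeric(demo["caseversion"], errors="coerce").fillna(0).astype(int)
    latest = demo.assign(_v=version_num).sort_values(["caseid", "_v"]).drop_duplicates("caseid", keep="last")

    selected = latest[rng.random(len(latest)) < duplicate_rate]
    if not len(selected):
        return cases
    n_extra = rng.integers(1, 3, size=len(selected))

    rep = selected.loc[np.repeat(selected.index, n_extra)].copy()
    offsets = np.concatenate([np.arange(1, k + 1) for k in n_extra])
    is_last = np.concatenate([np.arange(1, k + 1) == k for k in n_extra])
    new_version = rep["_v"].to_numpy() + offsets
    rep["caseversion"] = new_version.astype(str)
    rep["primaryid"] = [f"{cid}{v:02d}" for cid, v in zip(rep["caseid"], new_version)]

    # perturb intermediate (non-final) versions' demographics
    perturb = ~is_last
    if perturb.any():
        ages = rep["age"].to_numpy(object).copy()
        jitter = rng.integers(-2, 3, size=len(rep))
        for i in np.nonzero(perturb)[0]:
            if ages[i] not in ("", None):
                ages[i] = str(max(1, int(float(ages[i])) + int(jitter[i])))
        rep["age"] = ages
    new_demo = rep.drop(columns="_v")

    mapping = pd.DataFrame(
        {
            "caseid": rep["caseid"].to_numpy(object),
            "new_primaryid": rep["primaryid"].to_numpy(object),
            "orig_primaryid": selected.loc[np.repeat(selected.index, n_extra), "primaryid"].to_numpy(object),
        }
    )

    def _replicate(child: pd.DataFrame) -> pd.DataFrame:
        if not len(child):
            return child
        merged = child.merge(
            mapping[["orig_primaryid", "new_primaryid"]],
            left_on="primaryid",
            right_on="orig_primaryid",
            how="inner",
        )
        if not len(merged):
            return child
        merged["primaryid"] = merged["new_primaryid"]
        merged = merged[child.columns]
        return pd.concat([child, merged], ignore_index=True)

    return CaseReportSet(
        pd.concat([demo, new_demo], ignore_index=True).sort_values(["caseid", "caseversion"]).reset_index(drop=True),
        _replicate(cases.drugs).sort_values(["caseid", "primaryid"]).reset_index(drop=True),
        _replicate(cases.reactions).sort_values(["caseid", "primaryid"]).reset_index(drop=True),
        _replicate(cases.outcomes).sort_values(["caseid", "primaryid"]).reset_index(drop=True),
    )


# --- review posts ------------------------------------------------------------


@dataclass
class ReviewPostSet:
    """Simulated review posts plus the PT ground truth per post."""

    posts: pd.DataFrame  # post_id, drug_label, age_band, sex, duration_band, text, rating_only, non_ae_flag
    truth: dict[str, frozenset]

    def write_csv(self, path) -> None:
        self.posts.to_csv(path, index=False)

    def write_truth_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({k: sorted(v) for k, v in self.truth.items()}, fh, indent=2)


_NON_AE_TEXTS = [
    "Great price at my local pharmacy, ask your doctor about generics today.",
    "Does anyone know whether this comes in an extended release tablet?",
    "Visit our site for discount coupons on all prescriptions.",
]


def simulate_reviews(
    config: SimConfig,
    phrase_lexicon: Optional[Mapping[str, str]] = None,
    n_posts: Optional[int] = None,
) -> ReviewPostSet:
    """Generate drug-review posts whose free text embeds one lexicon phrase
    per generating PT, so a noise-free lexicon scan recovers the PT set.

    Rating-only posts (empty text) and non-AE posts (flagged) are mixed in
    at the configured rates; both carry an empty ground-truth PT set.
    """
    entries = dict(phrase_lexicon) if phrase_lexicon is not None else dict(resources.DEFAULT_PHRASE_LEXICON)
    if not entries:
        raise ConfigurationError("phrase lexicon is empty")
    n = config.n_posts if n_posts is None else n_posts
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2062]))

    by_pt: dict[str, list[str]] = {}
    for phrase, pt in entries.items():
        by_pt.setdefault(pt, []).append(phrase)
    pts = sorted(by_pt)
    weights = np.array([config.event_vocabulary.get(pt, 0.0) for pt in pts], float)
    if weights.sum() <= 0:
        weights = np.ones(len(pts))
    weights = weights / weights.sum()

    counts = np.array(sorted(config.pts_per_case_dist))
    count_p = np.array([config.pts_per_case_dist[k] for k in counts], float)
    count_p = count_p / count_p.sum()

    rows = []
    truth: dict[str, frozenset] = {}
    for i in range(n):
        post_id = f"P{i:06d}"
        u = rng.random()
        age_band = str(rng.choice(_AGE_BANDS_RAW, p=_AGE_BAND_P))
        sex = str(rng.choice(["F", "M", ""], p=[0.62, 0.33, 0.05]))
        duration = str(rng.choice(_DURATION_BANDS))
        if u < config.rating_only_rate:
            rows.append((post_id, config.target_drug, age_band, sex, duration, "", True, False))
            truth[post_id] = frozenset()
            continue
        if u < config.rating_only_rate + config.non_ae_rate:
            text = str(rng.choice(_NON_AE_TEXTS))
            rows.append((post_id, config.target_drug, age_band, sex, duration, text, False, True))
            truth[post_id] = frozenset()
            continue
        k = min(int(rng.choice(counts, p=count_p)), len(pts))
        chosen = rng.choice(len(pts), size=k, replace=False, p=weights)
        chosen_pts = [pts[j] for j in chosen]
        phrases = [str(rng.choice(by_pt[pt])) for pt in chosen_pts]
        text = f"After taking {config.target_drug}, I experienced " + ", and ".join(phrases) + "."
        rows.append((post_id, config.target_drug, age_band, sex, duration, text, False, False))
        truth[post_id] = frozenset(chosen_pts)

    posts = pd.DataFrame(
        rows,
        columns=["post_id", "drug_label", "age_band", "sex", "duration_band", "text", "rating_only", "non_ae_flag"],
    )
    return ReviewPostSet(posts=posts, truth=truth)
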