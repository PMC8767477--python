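# Methods

## Scope and data model

`pvsignal` screens one target drug for adverse-event signals in two data
streams: spontaneous case reports (DEMO/DRUG/REAC/OUTC tables in a
"$"-delimited ASCII dialect, one row per case version, joined on a primary
identifier) and patient drug-review posts (CSV with banded demographics and
free text). The counting unit everywhere is the *deduplicated case*: a PT
listed twice in one case counts once, while two distinct PTs in one case
count as two adverse events. Ages are banded <19, 19–64, ≥65 years (units
YR/MON/DY converted to years; months ÷ 12, days ÷ 365.25), with missing or
unrecognised values in an explicit Unknown band.

## Ingestion and deduplication

Resubmitted cases share a case id with a larger version stamp; "most
recent" means the maximum stamp (numeric when all stamps parse as numbers,
otherwise lexicographic). Equal stamps are broken deterministically by the
lexicographically greatest primary identifier, and every tie is logged.
Reports with no reaction rows, or whose only PTs are blank strings, carry
no analysable event and are dropped with a warning; so are reports with no
drug rows, since a case report without a drug cannot enter a drug–event
table. Target-drug retrieval is a case-insensitive exact match of trimmed
verbatim names against a synonym lexicon (generic plus brand names); no
fuzzy matching, trading recall for reproducibility. Retained cases must
carry the match in a primary- or secondary-suspect role (configurable), so
reports where the drug is merely concomitant or interacting do not count as
exposed.

## Disproportionality statistics

For each PT a 2×2 table (a, b, c, d) is built over the full deduplicated
universe (target + comparator reports; a restricted comparator is a
parameter). The measures are

- PRR = [a/(a+b)]/[c/(c+d)], 95% CI exp(ln PRR ± 1.96·se),
  se² = 1/a − 1/(a+b) + 1/c − 1/(c+d);
- ROR = ad/bc, 95% CI with se² = 1/a + 1/b + 1/c + 1/d;
- IC = log₂((a+0.5)/(E+0.5)), E = (a+b)(a+c)/N, with 95% credible interval
  log₂(g_q/(E+0.5)) for g_q the 0.025/0.975 quantiles of Gamma(a+0.5, 1).

Wald-type log-scale intervals are the standard pharmacovigilance choice for
PRR/ROR; the IC takes the widely used closed-form shrinkage form whose +0.5
offsets pull small-count estimates toward zero (|IC| ≤ |log₂(a/E)| always).
The test suite anchors these formulas against independent oracles: a ≥10⁶-
draw Monte-Carlo sample of the Gamma posterior (agreement within 0.02 bits
at each endpoint) and ≥10⁵-resample parametric bootstraps of the two
reporting proportions (PRR) and the multinomial table (ROR), whose
percentile intervals agree with the closed forms up to the small-count skew
a delta-method interval ignores (≲0.2 on the log scale at a = 20, c = 10).

**Zero cells.** No continuity correction is applied. A statistic requiring
a positive cell that is zero is reported as undefined (NaN, flagged) and
can never satisfy the criteria; this avoids manufacturing extreme ratios
from empty cells. The signal rule — PRR ≥ 2, ROR ≥ 2, a ≥ 3, IC025 > 0,
each threshold configurable — is verified exhaustively against a
from-scratch reimplementation over every table with N ≤ 30.

Ratios are displayed rounded to 1 decimal place and percentages to 2
(half-up, as tables print them); full precision is kept internally.

## Review-post annotation

Rating-only posts (empty text) and posts flagged as not AE-related are
excluded with per-reason counts. Free text is mapped to PTs by a
case-insensitive, longest-phrase-first, non-overlapping scan over a
phrase→PT lexicon; the mapper is a transparent, auditable stand-in for
human MedDRA coding. Negation is not handled ("no nausea" maps to Nausea)
and there is no spelling correction — both documented limitations. The
two-annotator workflow is modelled set-wise: the intersection of two
annotations is auto-accepted and the symmetric difference becomes a
disagreement queue that must be resolved through an explicit
(post_id, pt, decision, note) table; unresolved disagreements raise rather
than disappear.

## Signal classification

New-signal status is strict set membership against a user-supplied labelled
PT set; "incompletely described" label language cannot be machine-judged,
so PTs outside the working vocabulary go to a review list instead of being
classified. Seriousness uses outcome codes DE/LT/HO/DS (death,
life-threatening, hospitalization, disability) by default: a signal PT is
serious when the fraction of its supporting cases with ≥1 serious code
exceeds a strict threshold (default 0, i.e. any such case), or the PT is on
an always-serious override list; each flag records its rationale. PT→SOC
rollups require a user TSV (MedDRA is licensed and not redistributed; a
~100-term openly-written fixture vocabulary ships in `resources.py` for
tests and examples); unmapped PTs aggregate under "Others", totals are
conserved, and percentages sum to 100 within rounding.

## The synthetic-report generator

The generator's defaults are the package's study conditions and emulate the
structure disproportionality assumes, not any real database's joint
distribution.

* **Cases and drugs.** `n_cases` unique case identities; a case involves
  the target drug with probability `target_drug_prevalence` (default 0.10),
  drawing its role from `suspect_role_probs` (default PS 0.70, SS 0.18,
  C 0.09, I 0.03) and a concomitant background drug with probability 0.5;
  comparator cases get one background drug as primary suspect.
* **Events.** Each case draws a baseline PT count from `pts_per_case_dist`
  (default over 1–6, mean ≈ 3.3, echoing the several-PTs-per-patient
  structure of real report data) and that many categorical draws over the
  non-planted vocabulary (40 PTs with a head-and-tail weight profile,
  weights summing ≤ 1 per draw), keeping distinct terms — so every case has
  ≥1 PT and the baseline layer is identical for exposed and comparator
  cases. Each planted PT is instead an independent per-case Bernoulli:
  probability p (its stated background rate) in comparator cases and
  min(1, ρ·p) in target cases. The factor ρ therefore *equals* the
  asymptotic PRR, up to a small attenuation (~4%) because target-drug
  cases in concomitant/interacting roles stay in the comparator after the
  suspect filter.
* **Demographics and outcomes.** Age ~ round(Normal(50, 17)) clipped to
  1–95 years (≈3.4% under 19, ≈19% 65+), sex 55% F, country from a small
  ISO-like list; each field independently blanked at its missingness rate
  (defaults 0.25/0.10/0.05). Outcome codes are independent per-case
  Bernoullis (OT 0.25, HO 0.08, DE 0.02, LT 0.01, DS 0.01, CA 0.002,
  RI 0.005).
* **Duplicates.** With probability `duplicate_rate` (default 0.05) a case
  gains 1–2 extra versions with strictly later stamps; intermediate
  versions have jittered age, the latest is an exact content copy, so
  keep-most-recent deduplication restores the pre-injection content
  exactly (version stamp aside) — the round-trip the tests assert.
* **Review posts.** `n_posts` (default 2062) posts; 40% rating-only and 7%
  non-AE (flagged), matching roughly half of collected posts being
  unusable in review-site data. AE posts draw PTs from the lexicon's range
  (weighted by the event vocabulary) and embed exactly one surface phrase
  per PT in a fixed template, so a noise-free lexicon scan recovers the
  generating set exactly; real posts are messier in every way (negation,
  misspelling, paraphrase), which is precisely what this generator does
  not test.
* **Ground truth.** Planted pairs with ρ ≠ 1 are emitted as true
  associations; explicit ρ = 1 plants and all baseline PTs as null pairs.

Everything is driven by one integer seed through `numpy.random.default_rng`;
identical configurations produce identical output.

A design note: a single draw scheme cannot make both the per-case PT-count
distribution *and* the planted per-case presence probabilities exact. The
two-layer construction above gives exactness to the planted layer (where
calibration tests need binomial-exact rates) and leaves the count
distribution to the baseline layer; calibration tests that check a raw
presence probability use a one-draw-per-case configuration where baseline
presence equals the categorical weight exactly.

## Problem sizes and calibration checks

Recovery experiments use 50 seeded simulations of 20,000 cases with one
pair planted at ρ = 5 on background 0.002 (expected supporting count ≈ 18);
the full pipeline (simulate → duplicate injection → dedup → suspect filter
→ signals) recovers the planted pair in ≥ 90% of runs, and null pairs with
a ≥ 3 are flagged in ≤ 5% of pair-runs (observed: ~100% and ~0%). A
separate 20-seed null study with nothing planted checks the same false-
positive bound. These sizes keep the whole suite under a minute while
leaving the binomial-interval calibration checks (99% exact intervals at
n = 20,000–50,000) with decisive power.

## Known limitations

- Drug co-prescription is independent by construction; confounding by
  co-medication, the major real-world bias of disproportionality, is not
  emulated.
- Disproportionality measures association among reports, not causation or
  incidence; the package deliberately stops at signal flags plus
  label/seriousness bookkeeping.
- The lexicon mapper ignores negation, misspellings and paraphrase; its
  100% recovery on synthetic posts says nothing about recall on real text.
- Multi-item gamma-Poisson shrinkage (MGPS/EBGM), stratified or time-scan
  disproportionality, and probabilistic record linkage beyond case-id
  versioning are out of scope.
- Published full-database results (e.g. signal counts from millions of
  reports) depend on the complete extract and are not reproducible from
  synthetic data; the package reproduces the printed table arithmetic and
  the method's behaviour under known ground truth instead.
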