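"""Disproportionality statistics for drug-event pairs.

For each preferred term (PT), a 2x2 contingency table is built over a
deduplicated report universe:

    a = reports with the target drug and the event
    b = reports with the target drug, without the event
    c = other reports with the event
    d = other reports without the event

Three measures are computed with 95% intervals:

* PRR, the proportional reporting ratio  [a/(a+b)] / [c/(c+d)], with a
  Wald-type confidence interval on the log scale,
  exp(ln PRR +/- 1.96 * sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))).
* ROR, the reporting odds ratio  (a*d)/(b*c), with
  exp(ln ROR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)).
* IC, the information component  log2((a + 0.5) / (E + 0.5)) where
  E = (a+b)(a+c)/N is the expected count under independence. The 0.5 offsets
  shrink small-count estimates toward zero. The 95% credible interval treats
  the shrunken observed count as Gamma(a + 0.5, rate 1) distributed, so the
  endpoints are log2(gamma_q / (E + 0.5)) at q = 0.025 and 0.975.

A pair is a *signal* when PRR >= 2, ROR >= 2, a >= 3 and the IC credible
interval's lower limit exceeds 0 (all thresholds configurable).

Zero cells: no continuity correction is applied. A statistic whose formula
requires a positive cell that is zero is reported as undefined (NaN with
``defined=False``) and can never satisfy the signal criteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .types import CaseReportSet

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 drug-event counts (a, b, c, d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"cell {name}={v!r} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """E = (a+b)(a+c)/N, the count expected under independence."""
        if self.n == 0:
            raise ValidationError("empty table: N = 0")
        return (self.a + self.b) * (self.a + self.c) / self.n


@dataclass(frozen=True)
class IntervalEstimate:
    """A point estimate with a 95% interval; ``defined`` is False when a
    required cell was zero and the estimate is not computable."""

    estimate: float
    ci_low: float
    ci_high: float
    defined: bool = True

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.estimate, self.ci_low, self.ci_high)


_UNDEFINED = IntervalEstimate(math.nan, math.nan, math.nan, defined=False)


def prr(t: ContingencyTable) -> IntervalEstimate:
    """Proportional reporting ratio with 95% Wald CI on the log scale."""
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise ValidationError("PRR requires a+b > 0 and c+d > 0")
    if t.a == 0 or t.c == 0:
        return _UNDEFINED
    est = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    se = math.sqrt(1 / t.a - 1 / (t.a + t.b) + 1 / t.c - 1 / (t.c + t.d))
    return IntervalEstimate(est, est * math.exp(-Z_95 * se), est * math.exp(Z_95 * se))


def ror(t: ContingencyTable) -> IntervalEstimate:
    """Reporting odds ratio with 95% Wald CI on the log scale."""
    if t.a == 0 or t.b == 0 or t.c == 0 or t.d == 0:
        return _UNDEFINED
    est = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return IntervalEstimate(est, est * math.exp(-Z_95 * se), est * math.exp(Z_95 * se))


def ic(t: ContingencyTable) -> IntervalEstimate:
    """Shrunken information component with a 95% Gamma credible interval."""
    if t.n == 0:
        raise ValidationError("IC requires N > 0")
    e = t.expected
    est = math.log2((t.a + 0.5) / (e + 0.5))
    g = sps.gamma(a=t.a + 0.5, scale=1.0)
    low = math.log2(g.ppf(0.025) / (e + 0.5))
    high = math.log2(g.ppf(0.975) / (e + 0.5))
    return IntervalEstimate(est, low, high)


@dataclass
class SignalCriteria:
    """Threshold rule for signal detection."""

    prr_min: float = 2.0
    ror_min: float = 2.0
    min_count: int = 3
    ic_lower_min: float = 0.0

    def __post_init__(self) -> None:
        if min(self.prr_min, self.ror_min, self.min_count, self.ic_lower_min) < 0:
            raise ValidationError("signal thresholds must be >= 0")


@dataclass
class SignalStats:
    """All disproportionality estimates for one PT."""

    pt: str
    a: int
    expected: float
    prr: IntervalEstimate
    ror: IntervalEstimate
    ic: IntervalEstimate

    @classmethod
    def from_table(cls, pt: str, t: ContingencyTable) -> "SignalStats":
        return cls(pt=pt, a=t.a, expected=t.expected, prr=prr(t), ror=ror(t), ic=ic(t))


def evaluate_signal(stats: SignalStats, criteria: SignalCriteria = SignalCriteria()) -> tuple[bool, list[str]]:
    """Apply the threshold rule; returns (is_signal, names of failed criteria).

    Undefined PRR/ROR fail their criteria with reason "undefined".
    """
    failed: list[str] = []
    if not stats.prr.defined:
        failed.append("prr_undefined")
    elif stats.prr.estimate < criteria.prr_min:
        failed.append("prr")
    if not stats.ror.defined:
        failed.append("ror_undefined")
    elif stats.ror.estimate < criteria.ror_min:
        failed.append("ror")
    if stats.a < criteria.min_count:
        failed.append("min_count")
    if not stats.ic.defined or not (stats.ic.ci_low > criteria.ic_lower_min):
        failed.append("ic_lower")
    return (len(failed) == 0, failed)


# --- table construction ------------------------------------------------------


def build_contingency(universe: CaseReportSet, target_cases: CaseReportSet, pt: str) -> ContingencyTable:
    """2x2 table for one PT: target vs rest of the universe, counting each
    deduplicated case once per PT no matter how often the PT is listed."""
    universe_ids = set(universe.case_ids)
    target_ids = set(target_cases.case_ids)
    if not target_ids <= universe_ids:
        raise ValidationError("target cases must be a subset of the universe (by case id)")
    pairs = universe.case_pt_pairs()
    with_pt = set(pairs.loc[pairs["pt"] == pt, "caseid"])
    a = len(with_pt & target_ids)
    c = len(with_pt - target_ids)
    b = len(target_ids) - a
    d = len(universe_ids) - len(target_ids) - c
    return ContingencyTable(a, b, c, d)


def compute_signal_table(
    universe: CaseReportSet,
    target_cases: CaseReportSet,
    criteria: SignalCriteria = SignalCriteria(),
    pts: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Vectorised PRR/ROR/IC over every PT observed in the universe.

    Returns one row per PT with columns pt, a, expected, prr, prr_low,
    prr_high, ror, ror_low, ror_high, ic, ic_low, ic_high, is_signal,
    failed_criteria. Undefined ratios are NaN.
    """
    universe_ids = set(universe.case_ids)
    target_ids = set(target_cases.case_ids)
    if not target_ids <= universe_ids:
        raise ValidationError("target cases must be a subset of the universe (by case id)")
    n_universe = len(universe_ids)
    n_target = len(target_ids)
    pairs = universe.case_pt_pairs()
    if pts is not None:
        pairs = pairs[pairs["pt"].isin(set(pts))]
    if not len(pairs):
        cols = [
            "pt", "a", "expected", "prr", "prr_low", "prr_high", "ror", "ror_low",
            "ror_high", "ic", "ic_low", "ic_high", "is_signal", "failed_criteria",
        ]
        return pd.DataFrame(columns=cols)

    is_target = pairs["caseid"].isin(target_ids)
    grouped = pairs.assign(t=is_target).groupby("pt")["t"]
    a = grouped.sum().astype(int)
    ac = grouped.count().astype(int)
    df = pd.DataFrame({"pt": a.index, "a": a.values, "c": (ac - a).values})
    av = df["a"].to_numpy(float)
    cv = df["c"].to_numpy(float)
    bv = n_target - av
    dv = n_universe - n_target - cv
    nv = float(n_universe)

    with np.errstate(divide="ignore", invalid="ignore"):
        prr_est = np.where((av > 0) & (cv > 0), (av / (av + bv)) / (cv / (cv + dv)), np.nan)
        prr_se = np.sqrt(1 / av - 1 / (av + bv) + 1 / cv - 1 / (cv + dv))
        ror_est = np.where((av > 0) & (bv > 0) & (cv > 0) & (dv > 0), (av * dv) / (bv * cv), np.nan)
        ror_se = np.sqrt(1 / av + 1 / bv + 1 / cv + 1 / dv)
    expected = (av + bv) * (av + cv) / nv
    ic_est = np.log2((av + 0.5) / (expected + 0.5))
    g_low = sps.gamma.ppf(0.025, a=av + 0.5)
    g_high = sps.gamma.ppf(0.975, a=av + 0.5)
    ic_low = np.log2(g_low / (expected + 0.5))
    ic_high = np.log2(g_high / (expected + 0.5))

    out = pd.DataFrame(
        {
            "pt": df["pt"].values,
            "a": df["a"].values,
            "expected": expected,
            "prr": prr_est,
            "prr_low": prr_est * np.exp(-Z_95 * prr_se),
            "prr_high": prr_est * np.exp(Z_95 * prr_se),
            "ror": ror_est,
            "ror_low": ror_est * np.exp(-Z_95 * ror_se),
            "ror_high": ror_est * np.exp(Z_95 * ror_se),
            "ic": ic_est,
            "ic_low": ic_low,
            "ic_high": ic_high,
        }
    )
    failed = []
    for i in range(len(out)):
        f = []
        if np.isnan(prr_est[i]):
            f.append("prr_undefined")
        elif prr_est[i] < criteria.prr_min:
            f.append("prr")
        if np.isnan(ror_est[i]):
            f.append("ror_undefined")
        elif ror_est[i] < criteria.ror_min:
            f.append("ror")
        if out["a"].iat[i] < criteria.min_count:
            f.append("min_count")
        if not (ic_low[i] > criteria.ic_lower_min):
            f.append("ic_lower")
        failed.append(f)
    out["is_signal"] = [len(f) == 0 for f in failed]
    out["failed_criteria"] = [";".join(f) for f in failed]
    return out.sort_values("pt").reset_index(drop=True)
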