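"""End-to-end convenience: simulate -> dedup -> suspect filter -> signals."""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .disproportionality import SignalCriteria, compute_signal_table
from .ingest import DrugLexicon, deduplicate_cases, filter_target_drug
from .simulate import SignalTruth, SimConfig, simulate_reports
from .types import CaseReportSet


def signals_from_cases(
    cases: CaseReportSet,
    lexicon: DrugLexicon,
    criteria: SignalCriteria = SignalCriteria(),
    allowed_roles=("PS", "SS"),
) -> pd.DataFrame:
    """Deduplicate, apply the suspect-role drug filter, and compute the
    disproportionality signal table against the full deduplicated universe."""
    universe = deduplicate_cases(cases)
    target = filter_target_drug(universe, lexicon, allowed_roles=allowed_roles)
    return compute_signal_table(universe, target, criteria=criteria)


def run_simulation_pipeline(
    config: SimConfig,
    criteria: SignalCriteria = SignalCriteria(),
    lexicon: Optional[DrugLexicon] = None,
) -> tuple[pd.DataFrame, SignalTruth]:
    """Simulate reports under ``config`` and run the full detection pipeline."""
    cases, truth = simulate_reports(config)
    lex = lexicon or DrugLexicon(config.target_drug, {config.target_drug})
    return signals_from_cases(cases, lex, criteria=criteria), truth
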