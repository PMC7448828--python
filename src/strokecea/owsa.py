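"""One-way deterministic sensitivity analysis (tornado).

Each uncertain input is moved to its published low and high bound, one at
a time with everything else at base case, and the full model is
re-evaluated to obtain the ICER at each endpoint.  Entries are ordered by
the absolute ICER spread.  A composite entry replaces the thrombectomy
arm's 90-day mRS vector with configured low/high efficacy scenarios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

from . import decision_tree as dtree
from .econ import icer, nmb
from .markov import run_strategy
from .params import (
    LifeTable,
    ModelSettings,
    MrsDistribution,
    ParameterError,
    ParameterSet,
    SubgroupDefinition,
)

__all__ = ["TornadoEntry", "tornado_analysis", "deterministic_deltas", "tornado_to_frame"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_bound: float | str
    high_bound: float | str
    icer_at_low: float
    icer_at_high: float
    metric_at_low: float
    metric_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.metric_at_high - self.metric_at_low)


def deterministic_deltas(
    subgroup: SubgroupDefinition,
    params: ParameterSet,
    settings: ModelSettings,
    life_table: LifeTable,
    reference: MrsDistribution | None = None,
) -> tuple[float, float]:
    """One full deterministic evaluation: (delta_cost, delta_qaly)."""
    acute = dtree.evaluate_decision_tree(subgroup, params, reference)
    rec_cost, rec_util = dtree.recurrence_inputs(subgroup, params, acute)
    life = {}
    for name, arm in subgroup.arms.items():
        _, life[name] = run_strategy(arm, acute[name], params, settings, life_table,
                                     rec_cost[name], rec_util[name])
    return (
        life["MT_SMC"].discounted_cost - life["SMC"].discounted_cost,
        life["MT_SMC"].discounted_qaly - life["SMC"].discounted_qaly,
    )


def tornado_analysis(
    subgroup: SubgroupDefinition,
    params: ParameterSet,
    settings: ModelSettings,
    life_table: LifeTable,
    reference: MrsDistribution | None = None,
    use_nmb: bool = False,
    wtp: float = 100_000.0,
) -> list[TornadoEntry]:
    """Vary each parameter to its bounds; return entries sorted by spread.

    By default entries are ranked on ICER endpoints; ``use_nmb`` ranks on
    incremental net monetary benefit instead, which stays stable for
    dominance-heavy subgroups where ICER endpoints change sign.
    """

    def evaluate(p: ParameterSet, sub: SubgroupDefinition) -> tuple[float, float]:
        dc, dq = deterministic_deltas(sub, p, settings, life_table, reference)
        ratio, _ = icer(dc, dq)
        return ratio, (nmb(dc, dq, wtp) if use_nmb else ratio)

    entries: list[TornadoEntry] = []
    for path in params.scalar_paths():
        spec = params.specs[path]
        if spec.family == "fixed":
            continue
        if path.startswith("transitions.death_hr."):
            if not params.hr_sampled[int(path[-1])]:
                continue
        lo, hi = spec.bounds()
        base = params.get_value(path)
        if not (lo <= base <= hi):
            log.warning("skipping %s: base %s outside bounds (%s, %s)", path, base, lo, hi)
            continue
        try:
            icer_lo, m_lo = evaluate(params.with_value(path, lo), subgroup)
            icer_hi, m_hi = evaluate(params.with_value(path, hi), subgroup)
        except ParameterError as e:
            log.warning("skipping %s: bound violates validation (%s)", path, e)
            continue
        entries.append(TornadoEntry(path, lo, hi, icer_lo, icer_hi, m_lo, m_hi))

    # composite efficacy scenario for the thrombectomy arm
    scen = params.efficacy_scenarios
    if "mt_low_efficacy" in scen and "mt_high_efficacy" in scen:
        def with_mt_efficacy(d: MrsDistribution) -> SubgroupDefinition:
            arms = dict(subgroup.arms)
            arms["MT_SMC"] = replace(arms["MT_SMC"], efficacy=d, efficacy56=None)
            return replace(subgroup, arms=arms)

        icer_lo, m_lo = evaluate(params, with_mt_efficacy(scen["mt_low_efficacy"]))
        icer_hi, m_hi = evaluate(params, with_mt_efficacy(scen["mt_high_efficacy"]))
        entries.append(TornadoEntry("efficacy.mt_smc", "low_scenario", "high_scenario",
                                    icer_lo, icer_hi, m_lo, m_hi))

    entries.sort(key=lambda e: e.spread, reverse=True)
    return entries


def tornado_to_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low_bound,
                "high": e.high_bound,
                "icer_low": e.icer_at_low,
                "icer_high": e.icer_at_high,
                "spread": e.spread,
            }
            for e in entries
        ]
    )
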