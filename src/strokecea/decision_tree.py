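"""Short-run (90-day) decision tree.

Computes, per strategy, the expected acute-phase cost and expected utility
implied by the arm's 90-day mRS distribution.  The tree's only stochastic
node is the mRS outcome at 90 days plus fixed imaging-frequency mixes, so
it is evaluated as a cohort expectation rather than per-branch enumeration.

The two scalars it produces per strategy double as the strategy-specific
cost and utility of a recurrent stroke in the lifetime Markov model: a
recurrence is priced as "identify and treat a typical stroke under the same
strategy again".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    DEAD,
    N_ALIVE,
    CostInputs,
    MrsDistribution,
    ParameterError,
    ParameterSet,
    StrategyArm,
    SubgroupDefinition,
    UtilityInputs,
    validate_mrs_distribution,
)

__all__ = [
    "AcuteOutcome",
    "split_mrs56",
    "imaging_cost",
    "acute_expected_cost",
    "acute_expected_utility",
    "resolve_efficacy",
    "evaluate_decision_tree",
]


@dataclass(frozen=True)
class AcuteOutcome:
    """Per-strategy expected 90-day cost/utility and the mRS distribution."""

    strategy: str
    expected_cost_90d: float
    expected_utility: float
    mrs_at_90d: MrsDistribution


def split_mrs56(p56_combined: float, reference: MrsDistribution) -> tuple[float, float]:
    """Split combined mRS 5+6 mass by the reference's relative proportions.

    Some trial reports publish severe disability (mRS 5) and death (mRS 6)
    as one category; the mass is divided in the ratio observed in a
    reference trial that reported them separately.
    """
    if not (0.0 <= p56_combined <= 1.0):
        raise ParameterError("p56_combined", f"probability out of [0,1]: {p56_combined!r}")
    denom = reference.p[5] + reference.p[DEAD]
    if denom <= 0.0:
        raise ParameterError(
            "mrs56_reference", "reference has zero mass in mRS 5 and 6; split ratio undefined"
        )
    p5 = p56_combined * reference.p[5] / denom
    return p5, p56_combined - p5


def resolve_efficacy(arm: StrategyArm, reference: MrsDistribution | None = None) -> MrsDistribution:
    """Return the arm's 7-category mRS distribution, splitting a combined tail if needed."""
    if arm.efficacy is not None:
        return arm.efficacy
    if reference is None:
        raise ParameterError(
            "mrs56_reference", f"arm {arm.name} has combined mRS 5+6 input but no reference supplied"
        )
    p5, p6 = split_mrs56(arm.efficacy56[5], reference)
    return validate_mrs_distribution(arm.efficacy56[:5] + (p5, p6))


def imaging_cost(strategy: str, costs: CostInputs) -> float:
    """Expected imaging cost of the acute work-up.

    Standard care alone: CT + CTA.  Thrombectomy adds perfusion/diffusion
    selection imaging: CT, then CTA or MRA (frequency-weighted), CTP or MRI
    (frequency-weighted), plus infarct-volume software.
    """
    img = costs.imaging
    if strategy == "SMC":
        return img["ct"] + img["cta"]
    f, g = costs.freq_cta_vs_mra, costs.freq_ctp_vs_mri
    return (
        img["ct"]
        + f * img["cta"] + (1.0 - f) * img["mra"]
        + g * img["ctp"] + (1.0 - g) * img["mri"]
        + img["software"]
    )


def acute_expected_cost(
    arm: StrategyArm, costs: CostInputs, efficacy: MrsDistribution | None = None
) -> float:
    """Expected per-patient cost of the first 90 days.

    Imaging + frequency-weighted IV thrombolysis + (thrombectomy arm only)
    procedure and physician costs + severity-tiered acute care cost
    averaged over the 90-day mRS outcome.
    """
    eff = (efficacy or arm.efficacy).as_array()
    total = imaging_cost(arm.name, costs) + arm.tpa_frequency * costs.tpa_cost
    if arm.name == "MT_SMC":
        total += costs.mt_procedure + costs.mt_physician
    tiers = np.array([costs.acute_tier(i) for i in range(7)])
    return float(total + eff @ tiers)


def acute_expected_utility(efficacy: MrsDistribution, utilities: UtilityInputs) -> float:
    """Expected utility at 90 days: dot product of the mRS distribution with state utilities (death = 0)."""
    return float(efficacy.as_array() @ utilities.full_vector())


def evaluate_decision_tree(
    subgroup: SubgroupDefinition,
    params: ParameterSet,
    reference: MrsDistribution | None = None,
) -> dict[str, AcuteOutcome]:
    """Evaluate the 90-day tree for both arms of a subgroup.

    Returns one :class:`AcuteOutcome` per strategy.  The expected cost and
    utility serve downstream both as the acute-phase accruals and as the
    strategy-specific recurrent-stroke cost and recurrence utility.
    """
    out: dict[str, AcuteOutcome] = {}
    for name, arm in subgroup.arms.items():
        eff = resolve_efficacy(arm, reference)
        out[name] = AcuteOutcome(
            strategy=name,
            expected_cost_90d=acute_expected_cost(arm, params.costs, efficacy=eff),
            expected_utility=acute_expected_utility(eff, params.utilities),
            mrs_at_90d=eff,
        )
    return out


def recurrence_inputs(
    subgroup: SubgroupDefinition,
    params: ParameterSet,
    acute: dict[str, AcuteOutcome],
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-strategy recurrent-stroke cost and utility for the Markov model.

    Derived from the decision tree unless the parameter set pins explicit
    overrides (e.g. published totals for the full trial populations).
    """
    rc = {}
    ru = {}
    for name, outcome in acute.items():
        cost_override = (params.costs.recurrent_stroke_cost or {}).get(name)
        util_override = (params.utilities.recurrence_utility or {}).get(name)
        rc[name] = float(cost_override) if cost_override is not None else outcome.expected_cost_90d
        ru[name] = float(util_override) if util_override is not None else outcome.expected_utility
    return rc, ru
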