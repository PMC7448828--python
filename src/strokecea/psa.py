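"""Probabilistic sensitivity analysis.

Each draw samples one complete parameter set from the configured
uncertainty distributions, re-evaluates the decision tree (so the
recurrent-stroke cost/utility move with the drawn parameters rather than
being sampled independently), runs the Markov model for both strategies
with the same drawn values for shared parameters (common random numbers),
and records per-draw costs and QALYs.  Summaries are means and empirical
2.5/97.5 percentile credibility intervals; the cost-effectiveness
acceptability curve (CEAC) is the fraction of draws with positive
incremental net monetary benefit at each willingness-to-pay value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import decision_tree as dtree
from .econ import nmb
from .markov import run_strategy
from .params import (
    N_ALIVE,
    DistributionSpec,
    LifeTable,
    ModelSettings,
    MrsDistribution,
    ParameterError,
    ParameterSet,
    StrategyArm,
    SubgroupDefinition,
    validate_mrs_distribution,
)

__all__ = ["PsaResults", "sample_value", "sample_efficacy", "sample_parameter_set",
           "run_psa", "ceac"]

log = logging.getLogger(__name__)

_MAX_REJECT = 1000


def sample_value(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """Draw one value from a scalar distribution specification.

    beta-PERT uses the classic shape-4 parameterization
    ``alpha = 1 + 4 (mode - min)/(max - min)``,
    ``beta = 1 + 4 (max - mode)/(max - min)`` rescaled to [min, max];
    log-normal is median-preserving: ``exp(N(ln(base), se))``.
    """
    p = spec.params
    f = spec.family
    if f == "fixed":
        return p["value"]
    if f == "beta":
        return float(rng.beta(p["alpha"], p["beta"]))
    if f == "beta_pert":
        lo, mode, hi = p["min"], p["mode"], p["max"]
        span = hi - lo
        if span <= 0:
            return mode
        a = 1.0 + 4.0 * (mode - lo) / span
        b = 1.0 + 4.0 * (hi - mode) / span
        return float(lo + span * rng.beta(a, b))
    if f == "uniform":
        return float(rng.uniform(p["low"], p["high"]))
    if f == "log_normal":
        if p["se"] == 0.0:
            return p["base"]
        return float(np.exp(rng.normal(np.log(p["base"]), p["se"])))
    raise ParameterError("distribution.family", f"cannot scalar-sample family {f!r}")


def sample_efficacy(arm: StrategyArm, rng: np.random.Generator,
                    reference: MrsDistribution | None = None) -> MrsDistribution:
    """Dirichlet draw of the arm's 90-day mRS distribution.

    Concentration equals the observed arm counts ``n * p`` (multinomial
    conjugate), so larger subgroups draw tighter distributions.  Categories
    with zero observed mass stay at zero.
    """
    base = dtree.resolve_efficacy(arm, reference).as_array()
    conc = arm.n * base
    mask = conc > 0
    out = np.zeros_like(base)
    if mask.sum() == 1:
        out[mask] = 1.0
    else:
        out[mask] = rng.dirichlet(conc[mask])
    return validate_mrs_distribution(out)


def _all_fixed(params: ParameterSet) -> bool:
    """True when no input carries any sampling uncertainty."""
    for path, spec in params.specs.items():
        if spec.family == "fixed":
            continue
        if spec.family == "log_normal" and spec.params.get("se", 0.0) == 0.0:
            continue
        if path.startswith("transitions.death_hr."):
            if not params.hr_sampled[int(path[-1])]:
                continue
        return False
    return True


def sample_parameter_set(base: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """Redraw every uncertain scalar input; hazard ratios only where flagged.

    The post-recurrence destination split is redrawn as a flat Dirichlet
    over the strictly worse states, conditional on the drawn death share.
    Recurrent-stroke cost/utility overrides are cleared: they are
    recomputed from the drawn decision tree downstream.
    """
    if _all_fixed(base):
        return replace(
            base,
            costs=replace(base.costs, recurrent_stroke_cost=None),
            utilities=replace(base.utilities, recurrence_utility=None),
        )
    for _ in range(_MAX_REJECT):
        try:
            draw = base
            for path, spec in base.specs.items():
                if spec.family == "fixed":
                    continue
                if path.startswith("transitions.death_hr."):
                    i = int(path[-1])
                    if not base.hr_sampled[i]:
                        continue
                draw = draw.with_value(path, sample_value(spec, rng))
            split = tuple(
                tuple(rng.dirichlet(np.ones(N_ALIVE - 1 - i)))
                for i in range(N_ALIVE - 1)
            )
            draw = replace(
                draw,
                transitions=replace(draw.transitions, recurrence_split=split),
                costs=replace(draw.costs, recurrent_stroke_cost=None),
                utilities=replace(draw.utilities, recurrence_utility=None),
            )
            return draw
        except ParameterError as e:
            # e.g. sampled utilities violating monotonicity: reject and redraw
            log.debug("rejected parameter draw: %s", e)
            continue
    raise ParameterError("psa", f"could not draw a valid parameter set in {_MAX_REJECT} attempts")


@dataclass
class PsaResults:
    """Per-draw outcomes and summaries of one PSA run."""

    subgroup: str
    wtp_grid: tuple[float, ...]
    cost: dict[str, np.ndarray]      # strategy -> per-draw discounted cost
    qaly: dict[str, np.ndarray]
    n_rejected: int = 0

    @property
    def n_draws(self) -> int:
        return len(self.delta_cost)

    @property
    def delta_cost(self) -> np.ndarray:
        return self.cost["MT_SMC"] - self.cost["SMC"]

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.qaly["MT_SMC"] - self.qaly["SMC"]

    def nmb_draws(self, wtp: float) -> np.ndarray:
        return wtp * self.delta_qaly - self.delta_cost

    def prob_cost_effective(self, wtp: float) -> float:
        """Fraction of draws in which thrombectomy has the higher net benefit."""
        return float(np.mean(self.nmb_draws(wtp) > 0.0))

    def summary(self, wtp: float = 100_000.0) -> dict:
        """Means and empirical 95% credibility intervals of the increments."""
        def stats(a):
            lo, hi = np.percentile(a, [2.5, 97.5])
            return {"mean": float(np.mean(a)), "ci_low": float(lo), "ci_high": float(hi)}
        out = {
            "delta_cost": stats(self.delta_cost),
            "delta_qaly": stats(self.delta_qaly),
            "nmb": stats(self.nmb_draws(wtp)),
            "wtp": wtp,
            "n_draws": self.n_draws,
        }
        for strat in self.cost:
            out[f"cost_{strat}"] = stats(self.cost[strat])
            out[f"qaly_{strat}"] = stats(self.qaly[strat])
        return out

    def ceac(self, wtp_grid=None) -> pd.DataFrame:
        grid = tuple(wtp_grid) if wtp_grid is not None else self.wtp_grid
        return ceac(self, grid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "draw": np.arange(self.n_draws),
                "cost_mt_smc": self.cost["MT_SMC"],
                "qaly_mt_smc": self.qaly["MT_SMC"],
                "cost_smc": self.cost["SMC"],
                "qaly_smc": self.qaly["SMC"],
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qaly,
            }
        )


def ceac(results: PsaResults, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid."""
    grid = np.asarray(list(wtp_grid), dtype=float)
    prob = np.array([results.prob_cost_effective(w) for w in grid])
    return pd.DataFrame({"wtp": grid, "prob_cost_effective": prob})


def run_psa(
    subgroup: SubgroupDefinition,
    base_params: ParameterSet,
    settings: ModelSettings,
    life_table: LifeTable,
    reference: MrsDistribution | None = None,
    n_draws: int | None = None,
    seed: int | None = None,
) -> PsaResults:
    """Monte-Carlo propagation of parameter uncertainty for one subgroup.

    One master seed spawns an independent substream per draw, so any single
    draw can be reproduced in isolation.  Shared parameters (costs,
    utilities, transitions) are drawn once per draw and applied to both
    strategies; each arm's efficacy vector is drawn separately.
    """
    n = n_draws if n_draws is not None else settings.psa_draws
    master = seed if seed is not None else settings.seed
    streams = np.random.SeedSequence(master).spawn(n)

    cost = {s: np.empty(n) for s in subgroup.arms}
    qaly = {s: np.empty(n) for s in subgroup.arms}
    n_rejected = 0

    all_fixed = _all_fixed(base_params)
    for d, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        draw = sample_parameter_set(base_params, rng)
        if all_fixed:
            # no uncertain inputs: the efficacy draw degenerates to its base too
            drawn_sub = replace(
                subgroup,
                arms={
                    name: replace(arm, efficacy=dtree.resolve_efficacy(arm, reference),
                                  efficacy56=None)
                    for name, arm in subgroup.arms.items()
                },
            )
        else:
            drawn_sub = replace(
                subgroup,
                arms={
                    name: replace(arm, efficacy=sample_efficacy(arm, rng, reference),
                                  efficacy56=None)
                    for name, arm in subgroup.arms.items()
                },
            )
        acute = dtree.evaluate_decision_tree(drawn_sub, draw)
        rec_cost, rec_util = dtree.recurrence_inputs(drawn_sub, draw, acute)
        for name, arm in drawn_sub.arms.items():
            _, life = run_strategy(arm, acute[name], draw, settings, life_table,
                                   rec_cost[name], rec_util[name])
            cost[name][d] = life.discounted_cost
            qaly[name][d] = life.discounted_qaly

    return PsaResults(subgroup=subgroup.key, wtp_grid=settings.wtp_grid,
                      cost=cost, qaly=qaly, n_rejected=n_rejected)
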