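"""Lifetime Markov cohort model on 3-month cycles.

Patients surviving the 90-day acute phase enter mRS states 0..5 and are
propagated as cohort fractions until extinction.  Each cycle, every alive
state faces (in order):

1. background non-stroke death — life-table annual probability mixed across
   sexes, converted to a rate, scaled by the state's mortality hazard
   ratio, converted back to a 3-month probability;
2. recurrent stroke among background survivors (equal risk across states,
   at most one per cycle) — the recurring fraction either dies (fixed
   probability, replacing background mortality for that fraction) or moves
   to a strictly worse alive state, equally split;
3. everyone else remains in place (the structure forbids improvement).

Costs and QALYs accrue on end-of-transition status: non-recurrent
survivors accrue their state's 3-monthly long-term cost and utility,
recurring patients accrue the strategy's decision-tree-derived
recurrent-stroke cost and utility, background deaths accrue nothing that
cycle.  Accruals are discounted at the annual rate, compounded per cycle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decision_tree import AcuteOutcome
from .params import (
    DEAD,
    N_ALIVE,
    N_MRS,
    LifeTable,
    ModelSettings,
    MrsDistribution,
    ParameterError,
    ParameterSet,
    StrategyArm,
    TransitionInputs,
)

__all__ = [
    "CohortTrace",
    "LifetimeOutcome",
    "background_death_prob",
    "recurrence_outcome_distribution",
    "cycle_step",
    "run_markov",
    "run_strategy",
]

log = logging.getLogger(__name__)


@dataclass
class CohortTrace:
    """Cycle-by-state occupancy with per-cycle accruals.

    ``occupancy`` has one row per cycle boundary (row 0 = Markov entry) and
    7 columns (mRS 0..5 alive, death); rows sum to 1.  Accrual arrays have
    one entry per completed cycle.
    """

    ages: np.ndarray            # age at the END of each cycle (per accrual entry)
    occupancy: np.ndarray       # (n_cycles + 1, 7)
    disc_cost: np.ndarray       # discounted cost accrued in each cycle (per survivor)
    disc_qaly: np.ndarray       # discounted QALYs accrued in each cycle
    undisc_cost: np.ndarray
    undisc_qaly: np.ndarray
    recurrence: np.ndarray      # fraction of the entry cohort recurring in each cycle

    def to_frame(self) -> pd.DataFrame:
        n = len(self.ages)
        cols = {f"mrs{i}": self.occupancy[1:, i] for i in range(N_ALIVE)}
        cols["dead"] = self.occupancy[1:, DEAD]
        return pd.DataFrame(
            {"cycle": np.arange(1, n + 1), "age": self.ages, **cols,
             "disc_cost": self.disc_cost, "disc_qaly": self.disc_qaly,
             "recurrence": self.recurrence}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class LifetimeOutcome:
    """Per-patient lifetime totals for one strategy (acute phase included)."""

    strategy: str
    discounted_cost: float
    discounted_qaly: float
    undiscounted_cost: float
    undiscounted_qaly: float
    life_years: float


def background_death_prob(
    age: float, male_fraction: float, life_table: LifeTable, hr: float
) -> float:
    """HR-adjusted 3-month death probability from annual life-table ``qx``.

    The annual probability is mixed across sexes, converted to a hazard
    rate ``r = -ln(1 - qx)``, scaled by the hazard ratio, and converted to
    a quarter-year probability ``1 - exp(-hr * r / 4)``.  Applying the HR
    on the rate scale keeps the result a valid probability for any HR.
    """
    if hr <= 0:
        raise ParameterError("death_hr", f"hazard ratio must be > 0: {hr!r}")
    qx = life_table.qx(age, male_fraction)
    if qx >= 1.0:
        return 1.0
    r = -math.log1p(-qx)
    return -math.expm1(-hr * r * 0.25)


def recurrence_outcome_distribution(current: int, trans: TransitionInputs) -> np.ndarray:
    """Post-recurrence destination distribution over the 7 states.

    Death receives the fixed post-recurrence probability; the remainder is
    split equally among strictly worse alive states.  From mRS 5 no worse
    alive state exists, so survivors of a recurrence remain in mRS 5.
    """
    if not 0 <= current < N_ALIVE:
        raise ParameterError("mrs_state", f"current state must be mRS 0..5, got {current}")
    out = np.zeros(N_MRS)
    out[DEAD] = trans.post_recurrence_death
    survive = 1.0 - trans.post_recurrence_death
    worse = list(range(current + 1, N_ALIVE))
    if not worse:
        out[current] = survive
    elif trans.recurrence_split is not None:
        out[worse] = survive * np.asarray(trans.recurrence_split[current])
    else:
        out[worse] = survive / len(worse)
    return out


def _recurrence_matrix(trans: TransitionInputs) -> np.ndarray:
    return np.vstack([recurrence_outcome_distribution(i, trans) for i in range(N_ALIVE)])


def cycle_step(
    state_vector: np.ndarray,
    q_bg: np.ndarray,
    trans: TransitionInputs,
    rec_matrix: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Advance the cohort one cycle.

    Parameters
    ----------
    state_vector : occupancy over the 7 states (sums to 1).
    q_bg : per-state 3-month background death probabilities (length 6).
    rec_matrix : optional precomputed post-recurrence destination matrix.

    Returns ``(next_vector, staying, recurred)`` where ``staying`` is the
    per-state fraction that neither died nor recurred (the long-term
    accrual basis) and ``recurred`` the total recurring fraction.
    """
    x = np.asarray(state_vector, dtype=float)
    if abs(x.sum() - 1.0) > 1e-9:
        raise ParameterError("state_vector", f"occupancy sums to {x.sum()}, not 1")
    if rec_matrix is None:
        rec_matrix = _recurrence_matrix(trans)
    alive = x[:N_ALIVE]
    dead_bg = alive * q_bg
    survivors = alive - dead_bg
    rec = survivors * trans.recurrence_prob
    staying = survivors - rec
    nxt = np.zeros(N_MRS)
    nxt[:N_ALIVE] = staying
    nxt += rec @ rec_matrix
    nxt[DEAD] += x[DEAD] + dead_bg.sum()
    return nxt, staying, float(rec.sum())


def run_markov(
    initial: MrsDistribution,
    arm: StrategyArm,
    params: ParameterSet,
    settings: ModelSettings,
    life_table: LifeTable,
    recurrent_cost: float,
    recurrence_utility: float,
) -> tuple[CohortTrace, LifetimeOutcome]:
    """Propagate a 90-day survivor cohort to extinction.

    ``initial`` must carry no death mass (condition on survival first).
    Age advances a quarter-year per cycle from the arm's mean age; the life
    table applies from the end of month 3 onward, so the first cycle uses
    mortality at ``mean_age + 0.25``.  Totals here are per *survivor*;
    :func:`run_strategy` combines them with the acute phase.
    """
    x = initial.as_array().copy()
    if x[DEAD] > 1e-12:
        raise ParameterError("initial", "initial distribution must be conditioned on survival")

    trans = params.transitions
    rec_matrix = _recurrence_matrix(trans)
    hr = np.asarray(trans.death_hr)
    lt_cost = np.asarray(params.costs.longterm_3mo)
    util = np.asarray(params.utilities.utility)
    dt = settings.cycle_length
    disc = 1.0 / (1.0 + settings.discount_rate) ** dt  # per-cycle discount multiplier

    max_cycles = max(1, int(math.ceil((settings.max_age - arm.mean_age) / dt)))
    occ = [x.copy()]
    ages, d_cost, d_qaly, u_cost, u_qaly, recs = [], [], [], [], [], []
    alive_time = 0.0

    k = 0
    df = 1.0
    while k < max_cycles:
        k += 1
        age = arm.mean_age + dt * k
        qx = life_table.qx(age, arm.male_fraction)
        if qx >= 1.0:
            q_bg = np.ones(N_ALIVE)
        else:
            r = -math.log1p(-qx)
            q_bg = -np.expm1(-hr * r * dt)
        prev = x
        x, staying, rec_total = cycle_step(x, q_bg, trans, rec_matrix)
        df *= disc

        if settings.half_cycle_correction:
            # mid-cycle approximation: those dying or recurring during the
            # cycle contribute half a cycle of their origin state's accrual
            basis = 0.5 * (prev[:N_ALIVE] + staying)
        else:
            basis = staying
        cost = float(basis @ lt_cost + rec_total * recurrent_cost)
        qaly = dt * float(basis @ util + rec_total * recurrence_utility)

        occ.append(x.copy())
        ages.append(age)
        d_cost.append(df * cost)
        d_qaly.append(df * qaly)
        u_cost.append(cost)
        u_qaly.append(qaly)
        recs.append(rec_total)
        alive = 1.0 - x[DEAD]
        alive_time += dt * alive
        if alive < settings.extinction_tol:
            break
    else:
        if 1.0 - x[DEAD] >= settings.extinction_tol:
            log.warning(
                "cohort not extinct at max_age=%.0f (alive fraction %.2e); truncating",
                settings.max_age, 1.0 - x[DEAD],
            )

    trace = CohortTrace(
        ages=np.asarray(ages), occupancy=np.vstack(occ),
        disc_cost=np.asarray(d_cost), disc_qaly=np.asarray(d_qaly),
        undisc_cost=np.asarray(u_cost), undisc_qaly=np.asarray(u_qaly),
        recurrence=np.asarray(recs),
    )
    outcome = LifetimeOutcome(
        strategy=arm.name,
        discounted_cost=float(trace.disc_cost.sum()),
        discounted_qaly=float(trace.disc_qaly.sum()),
        undiscounted_cost=float(trace.undisc_cost.sum()),
        undiscounted_qaly=float(trace.undisc_qaly.sum()),
        life_years=alive_time,
    )
    return trace, outcome


def run_strategy(
    arm: StrategyArm,
    acute: AcuteOutcome,
    params: ParameterSet,
    settings: ModelSettings,
    life_table: LifeTable,
    recurrent_cost: float,
    recurrence_utility: float,
) -> tuple[CohortTrace, LifetimeOutcome]:
    """Acute phase + lifetime Markov phase, per initial patient.

    The acute-phase expected cost (and, when ``accrue_acute_qalys`` is set,
    a quarter-year of the 90-day expected utility) enters undiscounted at
    time zero.  Markov accruals are scaled by the 90-day survival fraction
    since only survivors enter the long-run model; 90-day deaths contribute
    their death-tier acute cost and zero utility.
    """
    p_dead = acute.mrs_at_90d.p_death
    survival = 1.0 - p_dead
    acute_qaly = settings.cycle_length * acute.expected_utility if settings.accrue_acute_qalys else 0.0

    if survival <= 0.0:
        empty = np.zeros(0)
        trace = CohortTrace(ages=empty, occupancy=acute.mrs_at_90d.as_array()[None, :],
                            disc_cost=empty, disc_qaly=empty,
                            undisc_cost=empty, undisc_qaly=empty, recurrence=empty)
        outcome = LifetimeOutcome(arm.name, acute.expected_cost_90d, acute_qaly,
                                  acute.expected_cost_90d, acute_qaly, 0.0)
        return trace, outcome

    trace, markov = run_markov(
        acute.mrs_at_90d.survivors(), arm, params, settings, life_table,
        recurrent_cost, recurrence_utility,
    )
    outcome = LifetimeOutcome(
        strategy=arm.name,
        discounted_cost=acute.expected_cost_90d + survival * markov.discounted_cost,
        discounted_qaly=acute_qaly + survival * markov.discounted_qaly,
        undiscounted_cost=acute.expected_cost_90d + survival * markov.undiscounted_cost,
        undiscounted_qaly=acute_qaly + survival * markov.undiscounted_qaly,
        life_years=settings.cycle_length + survival * markov.life_years,
    )
    return trace, outcome
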