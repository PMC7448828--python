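"""Independent per-patient stochastic microsimulation oracle.

Implements the same clinical rules as the cohort-expectation engine —
90-day mRS allocation, background death first (rate-scale hazard-ratio
adjustment), then at most one recurrent stroke per cycle with equal-split
worsening, end-of-transition accrual, per-cycle discounting — but by
simulating individual patients with random transitions instead of
propagating expectations.  Used only in tests, never by the package.
"""

from __future__ import annotations

import numpy as np

from strokecea.decision_tree import imaging_cost
from strokecea.params import ModelSettings, ParameterSet, StrategyArm, LifeTable

DEAD = 6


def microsimulate(
    arm: StrategyArm,
    params: ParameterSet,
    settings: ModelSettings,
    life_table: LifeTable,
    recurrent_cost: float,
    recurrence_utility: float,
    n_patients: int,
    rng: np.random.Generator,
):
    """Simulate ``n_patients`` through acute phase + lifetime follow-up.

    Returns ``(mean_cost, se_cost, mean_qaly, se_qaly)`` of per-patient
    discounted totals.
    """
    eff = arm.efficacy.as_array()
    costs, utils = params.costs, params.utilities
    trans = params.transitions
    dt = settings.cycle_length
    disc = 1.0 / (1.0 + settings.discount_rate) ** dt

    state = rng.choice(7, size=n_patients, p=eff).astype(np.int64)

    # acute phase: fixed resource components + severity-tiered care cost
    fixed = imaging_cost(arm.name, costs) + arm.tpa_frequency * costs.tpa_cost
    if arm.name == "MT_SMC":
        fixed += costs.mt_procedure + costs.mt_physician
    tier = np.array([costs.acute_tier(i) for i in range(7)])
    cost = fixed + tier[state]
    u_full = np.append(np.asarray(utils.utility), 0.0)
    qaly = dt * u_full[state] if settings.accrue_acute_qalys else np.zeros(n_patients)

    lt_cost = np.append(np.asarray(costs.longterm_3mo), 0.0)
    hr = np.append(np.asarray(trans.death_hr), 1.0)

    max_cycles = max(1, int(np.ceil((settings.max_age - arm.mean_age) / dt)))
    df = 1.0
    for k in range(1, max_cycles + 1):
        alive = state < DEAD
        if not alive.any():
            break
        df *= disc
        age = arm.mean_age + dt * k
        qx = life_table.qx(age, arm.male_fraction)
        if qx >= 1.0:
            q_state = np.ones(7)
        else:
            r = -np.log1p(-qx)
            q_state = -np.expm1(-hr * r * dt)

        u1 = rng.random(n_patients)
        die_bg = alive & (u1 < q_state[state])
        surv = alive & ~die_bg
        u2 = rng.random(n_patients)
        rec = surv & (u2 < trans.recurrence_prob)
        stay = surv & ~rec

        cost += df * (lt_cost[state] * stay + recurrent_cost * rec)
        qaly += df * dt * (u_full[state] * stay + recurrence_utility * rec)

        u3 = rng.random(n_patients)
        die_rec = rec & (u3 < trans.post_recurrence_death)
        move = rec & ~die_rec
        n_worse = 5 - state
        worsen = move & (n_worse > 0)
        u4 = rng.random(n_patients)
        new_state = state + 1 + np.floor(u4 * n_worse).astype(np.int64)
        state = np.where(worsen, np.minimum(new_state, 5), state)
        state = np.where(die_bg | die_rec, DEAD, state)

    return (
        float(cost.mean()), float(cost.std(ddof=1) / np.sqrt(n_patients)),
        float(qaly.mean()), float(qaly.std(ddof=1) / np.sqrt(n_patients)),
    )
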