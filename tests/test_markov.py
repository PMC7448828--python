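import math

import numpy as np
import pandas as pd
import pytest

from strokecea.markov import (
    background_death_prob,
    cycle_step,
    recurrence_outcome_distribution,
    run_markov,
    run_strategy,
)
from strokecea.decision_tree import AcuteOutcome
from strokecea.params import (
    CostInputs,
    LifeTable,
    ModelSettings,
    ParameterError,
    ParameterSet,
    StrategyArm,
    TransitionInputs,
    UtilityInputs,
    validate_mrs_distribution,
)
from strokecea.psa import sample_parameter_set


def _flat_life_table(qx: float, min_age=18, max_age=120) -> LifeTable:
    ages = np.arange(min_age, max_age + 1)
    return LifeTable(pd.DataFrame({
        "age": np.concatenate([ages, ages]),
        "sex": ["male"] * len(ages) + ["female"] * len(ages),
        "qx": np.full(2 * len(ages), qx),
    }))


def _arm(efficacy, name="SMC", age=70.0):
    return StrategyArm(name, mean_age=age, n=100, tpa_frequency=0.0,
                       efficacy=validate_mrs_distribution(efficacy))


SURVIVOR_UNIFORM = validate_mrs_distribution((1 / 6,) * 6 + (0.0,))


class TestBackgroundDeath:
    def test_rate_scale_conversion(self, life_table):
        lt = _flat_life_table(0.04)
        assert background_death_prob(70, 0.5, lt, 1.0) == pytest.approx(1 - 0.96**0.25)

    def test_hazard_ratio_scaling(self):
        lt = _flat_life_table(0.04)
        expected = 1 - math.exp(-2.37 * (-math.log(0.96)) / 4)
        assert background_death_prob(70, 0.5, lt, 2.37) == pytest.approx(expected)
        assert expected == pytest.approx(0.023897, abs=5e-7)

    def test_zero_mortality(self):
        lt = _flat_life_table(0.0)
        assert background_death_prob(70, 0.5, lt, 5.0) == 0.0

    def test_certain_death_stays_a_probability(self):
        lt = _flat_life_table(1.0)
        assert background_death_prob(70, 0.5, lt, 3.0) == 1.0

    def test_high_hazard_ratio_bounded_by_one(self):
        lt = _flat_life_table(0.5)
        q = background_death_prob(70, 0.5, lt, 50.0)
        assert 0.0 < q <= 1.0


class TestRecurrenceOutcome:
    @pytest.mark.parametrize(
        "state, n_worse, each",
        [(0, 5, (1 - 0.0513) / 5), (3, 2, (1 - 0.0513) / 2), (4, 1, 1 - 0.0513)],
    )
    def test_equal_split_matches_published_rounding(self, state, n_worse, each):
        d = recurrence_outcome_distribution(state, TransitionInputs())
        worse = d[state + 1: 6]
        assert len(worse) == n_worse
        assert np.allclose(worse, each)
        assert d[6] == pytest.approx(0.0513)
        # published rounded values: 0.19, 0.47, 0.95
        assert round(each, 2) in (0.19, 0.47, 0.95)

    def test_mrs5_recurrence_stays_or_dies(self):
        d = recurrence_outcome_distribution(5, TransitionInputs())
        assert d[5] == pytest.approx(1 - 0.0513)
        assert d[6] == pytest.approx(0.0513)

    def test_distribution_sums_to_one(self):
        t = TransitionInputs()
        for s in range(6):
            assert recurrence_outcome_distribution(s, t).sum() == pytest.approx(1.0)

    def test_custom_split_weights(self):
        t = TransitionInputs(recurrence_split=((0.5, 0.5, 0, 0, 0), (1, 0, 0, 0),
                                               (0.2, 0.8, 0), (0.3, 0.7), (1.0,)))
        d = recurrence_outcome_distribution(0, t)
        assert d[1] == pytest.approx(0.5 * (1 - 0.0513))
        assert d[3] == 0.0


class TestCycleStep:
    def test_identity_without_mortality_or_recurrence(self, base_params):
        x = SURVIVOR_UNIFORM.as_array()
        trans = TransitionInputs(recurrence_prob=0.0)
        from dataclasses import replace
        params = replace(base_params, transitions=trans)
        nxt, staying, rec = cycle_step(x, np.zeros(6), params.transitions)
        assert np.allclose(nxt, x)
        assert rec == 0.0

    def test_single_path_death_mass(self):
        x = np.zeros(7)
        x[5] = 1.0
        trans = TransitionInputs()
        nxt, _, rec = cycle_step(x, np.zeros(6), trans)
        assert nxt[6] == pytest.approx(0.013 * 0.0513, abs=1e-9)
        assert rec == pytest.approx(0.013)

    def test_probability_conservation(self, base_params, rng):
        x = rng.dirichlet(np.ones(7))
        q = rng.uniform(0, 0.3, size=6)
        nxt, _, _ = cycle_step(x, q, base_params.transitions)
        assert nxt.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_occupancy_rejected(self, base_params):
        with pytest.raises(ParameterError, match="sums"):
            cycle_step(np.full(7, 0.2), np.zeros(6), base_params.transitions)


class TestRunMarkov:
    def test_all_dead_initial_rejected_but_zero_survivor_handled(self, base_params, base_settings, life_table):
        dead = validate_mrs_distribution((0, 0, 0, 0, 0, 0, 1))
        arm = _arm((0, 0, 0, 0, 0, 0, 1))
        acute = AcuteOutcome("SMC", 24470.0, 0.0, dead)
        _, life = run_strategy(arm, acute, base_params, base_settings, life_table, 0.0, 0.0)
        assert life.discounted_cost == pytest.approx(24470.0)
        assert life.discounted_qaly == 0.0
        assert life.life_years == 0.0

    def test_closed_form_discount_sum(self, base_settings):
        """No death, no recurrence, utility 1, cost 0: QALYs are a geometric sum."""
        from dataclasses import replace
        lt = _flat_life_table(0.0)
        params = ParameterSet(
            transitions=TransitionInputs(recurrence_prob=0.0),
            costs=CostInputs(
                imaging={k: 0.0 for k in ("ct", "cta", "mri", "mra", "ctp", "software")},
                tpa_cost=0.0, mt_procedure=0.0, mt_physician=0.0,
                acute_90d={"mrs0_2": 0.0, "mrs3_5": 0.0, "death": 0.0},
                longterm_3mo=(0.0,) * 6,
            ),
            utilities=UtilityInputs(utility=(1.0,) * 6),
        )
        settings = replace(base_settings, max_age=90.0)
        arm = _arm((1, 0, 0, 0, 0, 0, 0), age=70.0)
        _, out = run_markov(validate_mrs_distribution((1, 0, 0, 0, 0, 0, 0)),
                            arm, params, settings, lt, 0.0, 0.0)
        n_cycles = math.ceil((90.0 - 70.0) / 0.25)
        expected = sum(0.25 * 1.03 ** (-0.25 * k) for k in range(1, n_cycles + 1))
        assert out.discounted_qaly == pytest.approx(expected, rel=1e-12)
        assert out.undiscounted_qaly == pytest.approx(0.25 * n_cycles, rel=1e-12)
        assert out.discounted_cost == 0.0

    def test_trace_conservation_and_absorption(self, base_params, base_settings, life_table):
        arm = _arm((0.2, 0.2, 0.2, 0.2, 0.1, 0.1, 0.0))
        trace, _ = run_markov(SURVIVOR_UNIFORM, arm, base_params, base_settings,
                              life_table, 30000.0, 0.4)
        sums = trace.occupancy.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        dead = trace.occupancy[:, 6]
        assert np.all(np.diff(dead) >= -1e-12)
        assert np.all(trace.occupancy >= -1e-12)
        assert 1.0 - dead[-1] < base_settings.extinction_tol

    def test_randomized_parameter_sets_preserve_invariants(
        self, base_params, base_settings, life_table
    ):
        """Conservation/absorption/non-negativity over many sampled inputs."""
        rng = np.random.default_rng(4)
        arm = _arm((0.2, 0.2, 0.2, 0.2, 0.1, 0.1, 0.0))
        for _ in range(25):
            draw = sample_parameter_set(base_params, rng)
            trace, _ = run_markov(SURVIVOR_UNIFORM, arm, draw, base_settings,
                                  life_table, 30000.0, 0.4)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(np.diff(trace.occupancy[:, 6]) >= -1e-12)
            assert np.all(trace.occupancy >= -1e-12)

    def test_raising_death_hr_decreases_qalys(self, base_params, base_settings, life_table):
        arm = _arm((0.2, 0.2, 0.2, 0.2, 0.1, 0.1, 0.0))
        base = run_markov(SURVIVOR_UNIFORM, arm, base_params, base_settings,
                          life_table, 30000.0, 0.4)[1]
        worse = base_params.with_value("transitions.death_hr.mrs4", 3.5)
        bumped = run_markov(SURVIVOR_UNIFORM, arm, worse, base_settings,
                            life_table, 30000.0, 0.4)[1]
        assert bumped.discounted_qaly < base.discounted_qaly
        assert bumped.life_years < base.life_years

    def test_raising_recurrence_decreases_qalys(self, base_params, base_settings, life_table):
        arm = _arm((0.2, 0.2, 0.2, 0.2, 0.1, 0.1, 0.0))
        base = run_markov(SURVIVOR_UNIFORM, arm, base_params, base_settings,
                          life_table, 30000.0, 0.4)[1]
        worse = base_params.with_value("transitions.recurrence_prob", 0.10)
        bumped = run_markov(SURVIVOR_UNIFORM, arm, worse, base_settings,
                            life_table, 30000.0, 0.4)[1]
        assert bumped.discounted_qaly < base.discounted_qaly

    def test_zero_discount_dominates_discounted(self, base_params, base_settings, life_table):
        from dataclasses import replace
        arm = _arm((0.2, 0.2, 0.2, 0.2, 0.1, 0.1, 0.0))
        disc = run_markov(SURVIVOR_UNIFORM, arm, base_params, base_settings,
                          life_table, 30000.0, 0.4)[1]
        undisc = run_markov(SURVIVOR_UNIFORM, arm, base_params,
                            replace(base_settings, discount_rate=0.0),
                            life_table, 30000.0, 0.4)[1]
        assert undisc.discounted_qaly > disc.discounted_qaly
        assert undisc.discounted_cost > disc.discounted_cost
        assert disc.discounted_qaly <= disc.undiscounted_qaly
        assert disc.discounted_cost <= disc.undiscounted_cost

    def test_half_cycle_correction_small_and_directional(
        self, base_params, base_settings, life_table
    ):
        from dataclasses import replace
        arm = _arm((0.2, 0.2, 0.2, 0.2, 0.1, 0.1, 0.0))
        std = run_markov(SURVIVOR_UNIFORM, arm, base_params, base_settings,
                         life_table, 30000.0, 0.4)[1]
        hcc = run_markov(SURVIVOR_UNIFORM, arm, base_params,
                         replace(base_settings, half_cycle_correction=True),
                         life_table, 30000.0, 0.4)[1]
        # mid-cycle accrual credits part of the dying fraction's cycle
        assert hcc.discounted_qaly > std.discounted_qaly
        assert abs(hcc.discounted_qaly - std.discounted_qaly) < 0.25

    def test_trace_csv_export(self, tmp_path, base_params, base_settings, life_table):
        arm = _arm((0.2, 0.2, 0.2, 0.2, 0.1, 0.1, 0.0))
        trace, _ = run_markov(SURVIVOR_UNIFORM, arm, base_params, base_settings,
                              life_table, 30000.0, 0.4)
        p = tmp_path / "trace.csv"
        trace.to_csv(p)
        df = pd.read_csv(p)
        assert {"cycle", "age", "mrs0", "dead", "disc_cost", "disc_qaly"} <= set(df.columns)
        assert len(df) == len(trace.ages)


class TestMicrosimulationOracle:
    """Cohort expectations vs an independent per-patient stochastic simulation."""

    @pytest.mark.parametrize("case", ["smc_base", "mt_base", "high_mortality"])
    def test_cohort_engine_matches_microsimulation(
        self, case, base_params, base_settings, life_table
    ):
        from _microsim import microsimulate
        efficacy = {
            "smc_base": ("SMC", (0.05, 0.08, 0.10, 0.15, 0.25, 0.22, 0.15), base_params),
            "mt_base": ("MT_SMC", (0.10, 0.23, 0.18, 0.13, 0.12, 0.09, 0.15), base_params),
            "high_mortality": (
                "SMC", (0.05, 0.08, 0.10, 0.15, 0.25, 0.22, 0.15),
                base_params.with_value("transitions.recurrence_prob", 0.05),
            ),
        }
        name, eff, params = efficacy[case]
        arm = StrategyArm(name, mean_age=70.0, n=100, tpa_frequency=0.1,
                          efficacy=validate_mrs_distribution(eff))
        from strokecea.decision_tree import acute_expected_cost, acute_expected_utility
        acute = AcuteOutcome(
            name,
            acute_expected_cost(arm, params.costs),
            acute_expected_utility(arm.efficacy, params.utilities),
            arm.efficacy,
        )
        rec_cost, rec_util = 35000.0, 0.45
        _, engine = run_strategy(arm, acute, params, base_settings, life_table,
                                 rec_cost, rec_util)
        import zlib
        n = 60_000
        rng = np.random.default_rng(zlib.crc32(case.encode()) % 2**31)
        m_cost, se_cost, m_qaly, se_qaly = microsimulate(
            arm, params, base_settings, life_table, rec_cost, rec_util, n, rng)
        assert abs(engine.discounted_cost - m_cost) < 3 * se_cost
        assert abs(engine.discounted_qaly - m_qaly) < 3 * se_qaly
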