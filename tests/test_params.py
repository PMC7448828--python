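import numpy as np
import pytest
import yaml
from hypothesis import given
from hypothesis import strategies as st

from strokecea.params import (
    DistributionSpec,
    LifeTable,
    MrsDistribution,
    ParameterError,
    StrategyArm,
    SubgroupDefinition,
    TransitionInputs,
    UtilityInputs,
    beta_from_range,
    load_parameters,
    save_parameters,
    subgroups_from_frame,
    efficacy_to_frame,
    validate_mrs_distribution,
)
from strokecea.synthetic import base_case_config_path

# Published base-case values the bundled config must carry verbatim.
TABLE1 = {
    "transitions.recurrence_prob": 0.013,
    "transitions.post_recurrence_death": 0.0513,
    "costs.imaging.ct": 198,
    "costs.imaging.cta": 774,
    "costs.imaging.mri": 625,
    "costs.imaging.mra": 1023,
    "costs.imaging.ctp": 836,
    "costs.imaging.software": 89,
    "costs.freq_cta_vs_mra": 0.5,
    "costs.freq_ctp_vs_mri": 0.5,
    "costs.tpa_cost": 8004,
    "costs.mt_procedure": 15836,
    "costs.mt_physician": 2749,
    "costs.acute_90d.mrs0_2": 14382,
    "costs.acute_90d.mrs3_5": 17879,
    "costs.acute_90d.death": 23498,
    "costs.longterm_3mo.mrs0": 2836,
    "costs.longterm_3mo.mrs1": 2741,
    "costs.longterm_3mo.mrs2": 3378,
    "costs.longterm_3mo.mrs3": 5801,
    "costs.longterm_3mo.mrs4": 11742,
    "costs.longterm_3mo.mrs5": 17262,
    "utilities.mrs0": 0.85,
    "utilities.mrs1": 0.80,
    "utilities.mrs2": 0.70,
    "utilities.mrs3": 0.51,
    "utilities.mrs4": 0.30,
    "utilities.mrs5": 0.15,
}


class TestMrsDistribution:
    def test_valid_vectors_accepted(self):
        high = (0.10, 0.23, 0.18, 0.13, 0.12, 0.09, 0.15)
        d = validate_mrs_distribution(high)
        assert np.allclose(d.as_array(), high)
        degenerate = validate_mrs_distribution((1, 0, 0, 0, 0, 0, 0))
        assert degenerate.p[0] == 1.0

    @pytest.mark.parametrize(
        "bad",
        [
            (0.2, 0.2, 0.2, 0.1, 0.1, 0.05, 0.05 - 0.1),  # negative entry
            (0.2, 0.2, 0.2, 0.1, 0.1, 0.05, 0.05 + 0.2),  # sums to 1.1
            (0.1,) * 7,                                     # sums to 0.7
            (0.25, 0.25, 0.25, 0.25),                       # wrong length
        ],
    )
    def test_invalid_vectors_rejected(self, bad):
        with pytest.raises(ParameterError):
            validate_mrs_distribution(bad)

    @given(st.lists(st.floats(0.01, 1.0), min_size=7, max_size=7))
    def test_any_normalized_vector_validates(self, raw):
        vec = np.asarray(raw) / np.sum(raw)
        d = validate_mrs_distribution(tuple(vec))
        assert abs(sum(d.p) - 1.0) < 1e-9

    def test_survivor_conditioning_removes_death_mass(self):
        d = validate_mrs_distribution((0.1, 0.1, 0.1, 0.1, 0.2, 0.2, 0.2))
        s = d.survivors()
        assert s.p_death == 0.0
        assert np.allclose(s.as_array()[:6], d.as_array()[:6] / 0.8)


class TestValidation:
    def test_utility_out_of_range_names_field(self):
        with pytest.raises(ParameterError, match="mrs2"):
            UtilityInputs(utility=(0.85, 0.80, 1.2, 0.51, 0.30, 0.15))

    def test_utility_monotonicity_enforced(self):
        with pytest.raises(ParameterError, match="non-increasing"):
            UtilityInputs(utility=(0.85, 0.90, 0.70, 0.51, 0.30, 0.15))

    def test_missing_death_hr_entry(self):
        with pytest.raises(ParameterError, match="death_hr"):
            TransitionInputs(death_hr=(1.0, 1.0, 1.11, 1.27, 1.71))

    def test_nonpositive_hazard_ratio(self):
        with pytest.raises(ParameterError, match="mrs5"):
            TransitionInputs(death_hr=(1, 1, 1.11, 1.27, 1.71, 0.0))

    def test_arm_bounds(self):
        eff = validate_mrs_distribution((0.2, 0.2, 0.2, 0.1, 0.1, 0.1, 0.1))
        with pytest.raises(ParameterError, match="mean_age"):
            StrategyArm("SMC", mean_age=110, n=50, tpa_frequency=0.1, efficacy=eff)
        with pytest.raises(ParameterError, match="tpa_frequency"):
            StrategyArm("SMC", mean_age=70, n=50, tpa_frequency=1.5, efficacy=eff)

    def test_subgroup_requires_both_strategies(self):
        eff = validate_mrs_distribution((0.2, 0.2, 0.2, 0.1, 0.1, 0.1, 0.1))
        arm = StrategyArm("SMC", mean_age=70, n=50, tpa_frequency=0.1, efficacy=eff)
        with pytest.raises(ParameterError, match="arms"):
            SubgroupDefinition(trial="DAWN", label="x", arms={"SMC": arm})


class TestDistributionSpec:
    def test_pert_ordering_enforced(self):
        with pytest.raises(ParameterError):
            DistributionSpec("beta_pert", {"min": 10, "mode": 5, "max": 20})

    def test_beta_positivity_enforced(self):
        with pytest.raises(ParameterError):
            DistributionSpec("beta", {"alpha": -1, "beta": 2})

    def test_beta_from_range_moment_match(self):
        a, b = beta_from_range(0.30, 0.10, 0.40)
        assert a / (a + b) == pytest.approx(0.30)
        sd = np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        assert sd == pytest.approx((0.40 - 0.10) / 3.92, rel=1e-6)

    def test_bounds_prefer_printed_range(self):
        spec = DistributionSpec("beta", {"alpha": 2, "beta": 5}, range=(0.1, 0.4))
        assert spec.bounds() == (0.1, 0.4)


class TestConfigLoading:
    def test_base_case_matches_published_values(self, base_params):
        for path, expected in TABLE1.items():
            assert base_params.get_value(path) == pytest.approx(expected), path
        assert base_params.transitions.death_hr == (1.0, 1.0, 1.11, 1.27, 1.71, 2.37)
        assert base_params.specs["transitions.recurrence_prob"].params == {
            "alpha": 13.0, "beta": 986.0}

    def test_every_uncertain_input_has_a_spec(self, base_params):
        for path in TABLE1:
            assert path in base_params.specs, path

    def test_settings_defaults(self, base_settings):
        assert base_settings.discount_rate == 0.03
        assert base_settings.cycle_length == 0.25
        assert base_settings.cohort_size == 1000
        assert base_settings.psa_draws == 2000

    def test_round_trip(self, tmp_path, base_params, base_settings):
        out = tmp_path / "roundtrip.yaml"
        save_parameters(base_params, base_settings, out)
        params2, settings2 = load_parameters(out)
        assert params2.transitions == base_params.transitions
        assert params2.costs == base_params.costs
        assert params2.utilities == base_params.utilities
        assert settings2 == base_settings
        for path, spec in base_params.specs.items():
            spec2 = params2.specs[path]
            assert spec2.family == spec.family, path
            assert spec2.params == pytest.approx(spec.params), path

    def test_invalid_utility_in_config_rejected(self, tmp_path):
        with open(base_case_config_path()) as fh:
            cfg = yaml.safe_load(fh)
        cfg["utilities"]["mrs2"]["base"] = 1.2
        bad = tmp_path / "bad.yaml"
        with open(bad, "w") as fh:
            yaml.safe_dump(cfg, fh)
        with pytest.raises(ParameterError, match="mrs2"):
            load_parameters(bad)

    def test_missing_field_named_in_error(self, tmp_path):
        with open(base_case_config_path()) as fh:
            cfg = yaml.safe_load(fh)
        del cfg["costs"]["mt_procedure"]
        bad = tmp_path / "bad.yaml"
        with open(bad, "w") as fh:
            yaml.safe_dump(cfg, fh)
        with pytest.raises(ParameterError, match="mt_procedure"):
            load_parameters(bad)


class TestParameterSetAccessors:
    def test_with_value_is_isolated(self, base_params):
        modified = base_params.with_value("costs.mt_procedure", 20000.0)
        assert modified.costs.mt_procedure == 20000.0
        assert base_params.costs.mt_procedure == 15836.0

    def test_with_value_revalidates(self, base_params):
        with pytest.raises(ParameterError):
            base_params.with_value("utilities.mrs3", 1.5)


class TestLifeTable:
    def test_sex_mixing(self, life_table):
        q_m = life_table.qx(70, male_fraction=1.0)
        q_f = life_table.qx(70, male_fraction=0.0)
        assert q_f < q_m
        assert life_table.qx(70, 0.5) == pytest.approx(0.5 * (q_m + q_f))

    def test_clamp_beyond_range_warns(self, life_table):
        import pandas as pd
        lt = LifeTable(life_table.to_frame())  # fresh instance (warning fires once)
        with pytest.warns(UserWarning, match="beyond life table"):
            q = lt.qx(150, 0.5)
        assert q == lt.qx(lt.max_age, 0.5)

    def test_csv_round_trip(self, tmp_path, life_table):
        p = tmp_path / "lt.csv"
        life_table.to_csv(p)
        lt2 = LifeTable.from_csv(p)
        assert lt2.qx(75, 0.4) == pytest.approx(life_table.qx(75, 0.4))

    def test_rejects_single_sex(self):
        import pandas as pd
        df = pd.DataFrame({"age": [60, 61], "sex": ["male", "male"], "qx": [0.01, 0.011]})
        with pytest.raises(ParameterError, match="sex"):
            LifeTable(df)


class TestEfficacyIO:
    def test_frame_round_trip(self, study):
        df = efficacy_to_frame(study.subgroups)
        rebuilt = subgroups_from_frame(df)
        assert [sg.key for sg in rebuilt] == [sg.key for sg in study.subgroups]
        for a, b in zip(rebuilt, study.subgroups):
            assert a.needs_mrs56_split == b.needs_mrs56_split
            for name in a.arms:
                if a.arms[name].efficacy is not None:
                    assert np.allclose(a.arms[name].efficacy.as_array(),
                                       b.arms[name].efficacy.as_array())
                else:
                    assert a.arms[name].efficacy56 == pytest.approx(b.arms[name].efficacy56)
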