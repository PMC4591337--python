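"""Parameter registry: base-case values, derivations, validation, round-trip."""

import math

import pytest
from hypothesis import given, strategies as st

from continence_ce.params import (ParameterSet,
                                  derive_cycle_probabilities,
                                  derive_improvement_utility, prepare,
                                  target_population, validate_parameter_set)


class TestBaseCase:
    @pytest.mark.parametrize("name,arm,expected", [
        ("detection_incident", "current", 0.504),
        ("detection_incident", "new", 0.64),
        ("strategy_cure", "current", 0.37),
        ("strategy_cure", "new", 0.39),
        ("gp_medication_improvement", "current", 0.63),
        ("ns_initial_success", "new", 0.31),
        ("utility_success", None, 0.8595),
        ("utility_incontinent", None, 0.8246),
        ("pads_failure", None, 97.70),
        ("formal_care_failure", None, 3859.38),
        ("consult_ns", None, 41.39),
        ("implementation_annual", None, 426496.0),
    ])
    def test_printed_inputs(self, ps, name, arm, expected):
        assert ps.get(name, arm) == pytest.approx(expected, abs=1e-12)

    def test_base_case_validates_cleanly(self, ps):
        report = validate_parameter_set(ps)
        assert report.ok, str(report)

    def test_roundtrip_is_exact(self, ps, tmp_path):
        path = tmp_path / "params.yaml"
        ps.to_yaml(path)
        back = prepare(ParameterSet.from_yaml(path))
        for scope, pv in ps.iter_entries():
            assert back.get(pv.name, scope) == ps.get(pv.name, scope), pv.name


class TestDerivations:
    def test_improvement_utility_is_the_midpoint(self):
        assert derive_improvement_utility(0.8595, 0.8246) == pytest.approx(0.84205)
        assert derive_improvement_utility(1.0, 0.0) == 0.5

    @given(u1=st.floats(0, 1), u2=st.floats(0, 1))
    def test_improvement_utility_lies_between_inputs(self, u1, u2):
        mid = derive_improvement_utility(u1, u2)
        assert min(u1, u2) <= mid <= max(u1, u2)
        assert derive_improvement_utility(u1, u1) == u1

    def test_cycle_probability_derivations(self, ps):
        derived = derive_cycle_probabilities(ps)
        assert derived.get("uti_excess_yearly") == pytest.approx(0.457 - 0.154)
        assert derived.get("uti_per_cycle") == pytest.approx(0.303 / 4)
        # fall 0.41% x fracture-given-fall 5.7% = 0.023% per cycle
        assert derived.get("fracture_per_cycle") == pytest.approx(0.0041 * 0.057,
                                                                  rel=1e-12)
        assert derived.get("fracture_per_cycle") * 100 == pytest.approx(0.023,
                                                                        abs=5e-4)

    def test_zero_falls_give_zero_fractures(self, ps):
        mod = ps.copy()
        mod.set_value("fall_per_cycle", 0.0)
        assert derive_cycle_probabilities(mod).get("fracture_per_cycle") == 0.0

    def test_yearly_rate_above_one_is_rejected(self, ps):
        mod = ps.copy()
        mod.set_value("uti_yearly_oab", 1.2)
        with pytest.raises(ValueError):
            derive_cycle_probabilities(mod)

    def test_rounded_uti_switch(self, ps):
        mod = ps.copy()
        mod.set_value("use_rounded_uti", 1)
        assert prepare(mod).get("uti_per_cycle") == 0.08

    def test_ns_salary_derivation(self, ps):
        assert ps.get("ns_annual_salary") == pytest.approx(44736.0)
        assert ps.get("ns_hourly_wage") == pytest.approx(44736.0 / 1540.0)

    def test_care_cost_reductions_regenerate_state_costs(self, ps):
        assert ps.get("formal_care_improvement") == pytest.approx(3473.44, abs=0.01)
        assert ps.get("formal_care_success") == pytest.approx(2894.53, abs=0.01)
        assert ps.get("informal_care_improvement") == pytest.approx(1916.09, abs=0.01)
        assert ps.get("informal_care_success") == pytest.approx(1596.75, abs=0.01)


class TestValidation:
    def test_branch_sum_violation_is_reported(self, ps):
        mod = ps.copy()
        mod.set_value("gp_rx_medication", 0.9, arm="current")  # 0.9+0.17+0.04 > 1.01
        report = validate_parameter_set(mod)
        assert any("branch sum" in v for v in report.violations)

    def test_utility_out_of_range_is_reported(self, ps):
        mod = ps.copy()
        mod.set_value("utility_success", 1.2)
        report = validate_parameter_set(mod)
        assert any("out of [0,1]" in v for v in report.violations)

    def test_missing_required_name_is_reported(self, ps):
        mod = ps.copy()
        del mod.current["gp_rx_medication"]
        report = validate_parameter_set(mod)
        assert any("incomplete set" in v for v in report.violations)

    def test_negative_cost_is_reported(self, ps):
        mod = ps.copy()
        mod.set_value("consult_gp", -1.0)
        report = validate_parameter_set(mod)
        assert any("negative cost" in v for v in report.violations)


class TestPopulation:
    def test_printed_population_arithmetic(self, ps):
        pop = target_population(ps)
        assert pop["eligible"] == 808_503
        assert pop["incident_yearly"] == 25_872
        assert pop["prevalent"] == 58_306
        assert pop["prevalent_women"] == 44_896
        assert pop["prevalent_men"] == 13_410

    def test_zero_incidence_gives_zero_cases(self, ps):
        mod = ps.copy()
        mod.set_value("ui_incidence_yearly", 0.0)
        assert target_population(mod)["incident_yearly"] == 0

    def test_incident_count_scales_with_incidence(self, ps):
        pop = target_population(ps)
        assert pop["incident_yearly"] == math.floor(808_503 * 0.032)
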