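"""Costing and QALY accrual: closed forms, perspective algebra, a
spreadsheet-style hand expansion of a toy cycle."""

import pytest

from continence_ce import economics as ec
from continence_ce import pathway as pw
from continence_ce.params import prepare
from continence_ce.synthetic import generate_random_parameter_set


def _trace_with_constant_state(state, ps, cycles=12):
    vecs = []
    for _ in range(cycles + 1):
        v = pw.zero_vec()
        v[state] = 1.0
        vecs.append(v)
    return pw.CohortTrace(arm="current", cohort="incident", vecs=vecs,
                          events=[pw.zero_events() for _ in range(cycles)])


class TestQalys:
    def test_all_incontinent_closed_form(self, ps):
        trace = _trace_with_constant_state(pw.UNDET, ps)
        assert ec.total_qalys(trace, ps) == pytest.approx(3 * 0.8246)

    def test_all_success_closed_form(self, ps):
        trace = _trace_with_constant_state(pw.SUCC, ps)
        assert ec.total_qalys(trace, ps) == pytest.approx(3 * 0.8595)

    def test_qalys_bounded_by_extreme_states(self, ps):
        for arm in ("current", "new"):
            for cohort in ("incident", "prevalent"):
                trace = pw.run_cohort(arm, cohort, ps, prepared=True)
                q = ec.total_qalys(trace, ps)
                assert 3 * 0.8246 - 1e-9 <= q <= 3 * 0.8595 + 1e-9

    def test_mixed_cohort_qalys_match_published_totals(self, base_results):
        assert base_results.current.qalys == pytest.approx(2.4777, abs=0.005)
        assert base_results.new.qalys == pytest.approx(2.4829, abs=0.005)


class TestCycleCosts:
    def test_success_state_has_no_containment_cost(self, ps):
        v = pw.zero_vec()
        v[pw.SUCC] = 1.0
        cv = ec.cycle_cost_vector(v, pw.zero_events(), 2, "current", ps)
        assert cv.eur["containment_insured"] == 0.0
        assert cv.eur["out_of_pocket_containment"] == 0.0

    def test_hand_expanded_toy_cycle_matches_to_the_cent(self, ps):
        """Spreadsheet-style expansion: 40% insured containment, 30%
        undetected, 20% improved, 10% success, with 0.1 GP consultations
        and 0.2 medication dispensings booked in the cycle."""
        v = pw.zero_vec()
        v[pw.CONT] = 0.4
        v[pw.UNDET] = 0.3
        v[pw.IMP_IN] = 0.2
        v[pw.SUCC] = 0.1
        events = pw.zero_events()
        events["gp_consult"] = 0.1
        events["med_gp_ns"] = 0.2
        cv = ec.cycle_cost_vector(v, events, 2, "current", ps)
        assert cv.eur["gp_ns"] == pytest.approx(0.1 * 30.48 + 0.2 * 114.96, abs=1e-9)
        assert cv.eur["containment_insured"] == pytest.approx(
            0.4 * 97.70 + 0.2 * 71.22, abs=1e-9)
        assert cv.eur["out_of_pocket_containment"] == pytest.approx(0.3 * 97.70)
        assert cv.eur["travel"] == pytest.approx(0.1 * 3.51)
        # formal care: 47% of state-dependent yearly-quarter amounts
        assert cv.eur["formal_home_care"] == pytest.approx(
            0.47 * (0.7 * 3859.38 + 0.2 * 3473.442 + 0.1 * 2894.535), abs=1e-6)
        assert cv.eur["informal_care"] == pytest.approx(
            0.43 * (0.7 * 2128.99 + 0.2 * 1916.091 + 0.1 * 1596.7425), abs=1e-6)
        # adverse events hit the non-success mass
        ae = (0.303 / 4) * 2.51 + (0.0041 * 0.057) * 2944.36 + 0.08 * 6.49
        assert cv.eur["adverse_events"] == pytest.approx(0.9 * ae, abs=1e-9)

    def test_cost_shift_self_management_to_containment(self, ps):
        """Moving a patient from self-management to insured containment
        leaves the societal pad bill unchanged but raises the payer bill."""
        v1 = pw.zero_vec()
        v1[pw.SELF] = 1.0
        v2 = pw.zero_vec()
        v2[pw.CONT] = 1.0
        c1 = ec.cycle_cost_vector(v1, pw.zero_events(), 2, "current", ps)
        c2 = ec.cycle_cost_vector(v2, pw.zero_events(), 2, "current", ps)
        pads1 = c1.eur["containment_insured"] + c1.eur["out_of_pocket_containment"]
        pads2 = c2.eur["containment_insured"] + c2.eur["out_of_pocket_containment"]
        assert pads1 == pytest.approx(pads2)
        assert c2.payer_total > c1.payer_total
        assert c2.societal_total == pytest.approx(c1.societal_total)


class TestResultsTable:
    def test_societal_total_nests_payer_total(self, ps, base_results):
        for arm in ("current", "new"):
            ar = getattr(base_results, arm)
            assert ar.costs.societal_total >= ar.costs.payer_total
        for seed in range(5):
            rt = ec.per_patient_results(generate_random_parameter_set(seed, ps))
            for arm in ("current", "new"):
                costs = getattr(rt, arm).costs
                assert costs.societal_total >= costs.payer_total

    def test_incremental_equals_sum_of_components(self, base_results):
        delta = base_results.delta_costs
        assert base_results.delta_societal == pytest.approx(
            sum(delta.eur.values()), abs=1e-9)
        assert base_results.delta_payer == pytest.approx(
            sum(delta.eur[c] for c in ec.PAYER_CATEGORIES), abs=1e-9)

    def test_published_cost_rows(self, base_results):
        """Occupancy-driven cost rows against the published per-patient
        table (home care, informal care, out-of-pocket, containment)."""
        cur, new = base_results.current.costs, base_results.new.costs
        assert cur.eur["formal_home_care"] == pytest.approx(21576, rel=0.02)
        assert new.eur["formal_home_care"] == pytest.approx(21323, rel=0.02)
        assert cur.eur["informal_care"] == pytest.approx(10889, rel=0.02)
        oop_cur = cur.eur["out_of_pocket_containment"] + cur.eur["travel"]
        assert oop_cur == pytest.approx(700, rel=0.05)
        assert cur.eur["containment_insured"] == pytest.approx(436, rel=0.05)


class TestImplementation:
    def test_per_patient_share_of_annual_cost(self, ps):
        assert ec.implementation_cost_per_patient(ps) == pytest.approx(
            426496.0 / (58306 + 25872), rel=1e-9)

    def test_full_share_scales_annual_cost(self, ps):
        mod = ps.copy()
        mod.set_value("implementation_share", 1.0)
        assert ec.implementation_cost_per_patient(mod) == pytest.approx(
            426496.0 / 0.238 / (58306 + 25872), rel=1e-9)

    def test_empty_population_is_an_error(self, ps):
        mod = prepare(ps.copy())
        mod.set_value("n_prevalent", 0)
        mod.set_value("n_eligible", 0)
        with pytest.raises(ZeroDivisionError):
            ec.implementation_cost_per_patient(mod)

    def test_parameter_identical_arms_differ_only_by_implementation(self, ps):
        """When the NS arm mirrors current care exactly, the incremental
        cost is the implementation fee and the QALY gain is zero."""
        from continence_ce.params import ParameterValue

        mod = ps.copy()
        mod.new = {
            "ns_first_line": ParameterValue("ns_first_line", 1.0, "fraction"),
            "ns_detection_gain": ParameterValue("ns_detection_gain", 0.0, "probability"),
            "extra_detection": ParameterValue("extra_detection", 0.0, "probability"),
        }
        # NS consultations at the GP tariff to make the arms cost-identical,
        # all assessments at the GP, and the prevalent residual cure mass
        # routed to the GP lane in both arms
        mod.set_value("consult_ns", mod.get("consult_gp"))
        mod.set_value("assess_gp", 1.0, arm="current")
        mod.set_value("assess_ppt", 0.0, arm="current")
        mod.set_value("prevalent_cure_gp", 1.0, arm="current")
        mod.set_value("prevalent_cure_ppt", 0.0, arm="current")
        mod.set_value("prevalent_cure_specialist", 0.0, arm="current")
        rt = ec.per_patient_results(mod)
        assert rt.delta_qalys == pytest.approx(0.0, abs=1e-12)
        assert rt.delta_payer == pytest.approx(
            ec.implementation_cost_per_patient(prepare(mod)), abs=1e-9)
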