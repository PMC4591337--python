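"""Costing and QALY accrual over cohort traces.

Costs are accumulated per category so the per-patient results table can be
reported from both the health-care payer perspective (consultations and
treatment, insured containment, adverse events, formal home care,
implementation) and the societal perspective (payer plus travel,
out-of-pocket containment and informal care).  All amounts are 2013 euros
per patient; no discounting is applied over the 3-year horizon and no
half-cycle correction is used — state-dependent amounts are booked on the
end-of-cycle distribution, event costs in the cycle they occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import pathway as pw
from .params import ParameterSet, prepare, target_population

PAYER_CATEGORIES = ("gp_ns", "ppt", "specialist", "containment_insured",
                    "adverse_events", "formal_home_care", "implementation")
SOCIETAL_EXTRA = ("travel", "out_of_pocket_containment", "informal_care")
CATEGORIES = PAYER_CATEGORIES + SOCIETAL_EXTRA


@dataclass
class CostVector:
    """Euro amounts per category attributable to one cohort (per patient)."""

    eur: dict[str, float] = field(default_factory=lambda: dict.fromkeys(CATEGORIES, 0.0))

    def __post_init__(self):
        for c in CATEGORIES:
            self.eur.setdefault(c, 0.0)

    @property
    def payer_total(self) -> float:
        return sum(self.eur[c] for c in PAYER_CATEGORIES)

    @property
    def societal_total(self) -> float:
        return self.payer_total + sum(self.eur[c] for c in SOCIETAL_EXTRA)

    def __add__(self, other: "CostVector") -> "CostVector":
        return CostVector({c: self.eur[c] + other.eur[c] for c in CATEGORIES})

    def __sub__(self, other: "CostVector") -> "CostVector":
        return CostVector({c: self.eur[c] - other.eur[c] for c in CATEGORIES})

    def scaled(self, k: float) -> "CostVector":
        return CostVector({c: self.eur[c] * k for c in CATEGORIES})


def implementation_cost_per_patient(ps: ParameterSet,
                                    population: dict[str, int] | None = None) -> float:
    """One-off implementation cost per modelled patient in the new arm.

    The annual training/education cost carried by this population
    (``implementation_annual`` already reflects the base-case share of the
    total continence population; ``implementation_share`` scales it, with
    1.0 assigning the full cost) divided by the national patient pool
    (prevalent + yearly incident cases).
    """
    if population is None:
        population = target_population(ps)
    pool = population["prevalent"] + population["incident_yearly"]
    if pool <= 0:
        raise ZeroDivisionError("empty modelled population")
    base_share = 0.238  # share embedded in the printed annual figure
    annual = ps.get("implementation_annual") / base_share * ps.get("implementation_share")
    return annual / pool


def cycle_cost_vector(dist: dict[str, float], events: dict[str, float],
                      cycle: int, arm: str, ps: ParameterSet,
                      cohort: str = "incident") -> CostVector:
    """Costs booked for one cycle given the end-of-cycle distribution and
    the consultation/treatment events of that cycle."""
    g = ps.get
    cv = CostVector()
    e = cv.eur

    e["gp_ns"] = (events["gp_consult"] * g("consult_gp")
                  + events["ns_consult"] * g("consult_ns")
                  + events["med_gp_ns"] * g("medication_gp_ns")
                  + events["lifestyle"] * g("lifestyle_gp")
                  + events["training_gp"] * g("training_gp")
                  + events["uti_rx"] * g("uti_treatment_gp_ns"))
    e["ppt"] = (events["ppt_consult"] * g("consult_ppt")
                + events["pfmt"] * g("pfmt_ppt")
                + events["biofeedback"] * g("biofeedback_ppt"))
    e["specialist"] = (events["specialist_consult"] * g("consult_specialist")
                       + events["surgery"] * g("surgery_specialist")
                       + events["med_specialist"] * g("medication_specialist")
                       + events["conservative"] * g("conservative_specialist"))
    e["travel"] = ((events["gp_consult"] + events["ns_consult"]) * g("travel_gp_ns")
                   + events["ppt_consult"] * g("travel_ppt")
                   + events["specialist_consult"] * g("travel_specialist"))

    insured_fail = sum(dist[s] for s in pw.INSURED_FAILURE_STATES)
    improved = sum(dist[s] for s in pw.IMPROVED_STATES)
    succ = dist[pw.SUCC]
    oop_fail = dist[pw.UNDET] + dist[pw.SELF]
    fail_all = insured_fail + oop_fail

    e["containment_insured"] = (insured_fail * g("pads_failure")
                                + improved * g("pads_improvement")
                                + succ * g("pads_success"))
    e["out_of_pocket_containment"] = oop_fail * g("oop_pads")

    non_success = 1.0 - succ
    e["adverse_events"] = non_success * (g("uti_per_cycle") * g("uti_event")
                                         + g("fracture_per_cycle") * g("fracture_event")
                                         + g("skin_per_cycle") * g("skin_event"))

    e["formal_home_care"] = g("formal_care_share") * (
        fail_all * g("formal_care_failure")
        + improved * g("formal_care_improvement")
        + succ * g("formal_care_success"))
    e["informal_care"] = g("informal_care_share") * (
        fail_all * g("informal_care_failure")
        + improved * g("informal_care_improvement")
        + succ * g("informal_care_success"))

    if arm == "new" and cycle == 1:
        e["implementation"] = implementation_cost_per_patient(ps)
    return cv


def trace_costs(trace: pw.CohortTrace, ps: ParameterSet) -> list[CostVector]:
    """Per-cycle cost vectors for a cohort trace."""
    return [cycle_cost_vector(trace.vecs[t], trace.events[t - 1], t, trace.arm,
                              ps, trace.cohort)
            for t in range(1, trace.horizon + 1)]


def total_costs(trace: pw.CohortTrace, ps: ParameterSet) -> CostVector:
    out = CostVector()
    for cv in trace_costs(trace, ps):
        out = out + cv
    return out


def total_qalys(trace: pw.CohortTrace, ps: ParameterSet) -> float:
    """QALYs per patient: cycle length times state utility summed over the
    end-of-cycle occupancies; exited successes keep accruing the success
    utility."""
    dt = ps.get("cycle_length_years")
    u_f = ps.get("utility_incontinent")
    u_i = ps.get("utility_improvement")
    u_s = ps.get("utility_success")
    q = 0.0
    for t in range(1, trace.horizon + 1):
        fail, imp, succ = trace.occupancy(t)
        q += dt * (fail * u_f + imp * u_i + succ * u_s)
    return q


@dataclass
class ArmResult:
    costs: CostVector
    qalys: float
    outcomes: dict[str, pw.OutcomeSummary]


@dataclass
class ResultsTable:
    """Per-patient 3-year costs and QALYs for both arms plus incrementals."""

    current: ArmResult
    new: ArmResult

    @property
    def delta_costs(self) -> CostVector:
        return self.new.costs - self.current.costs

    @property
    def delta_qalys(self) -> float:
        return self.new.qalys - self.current.qalys

    @property
    def delta_payer(self) -> float:
        return self.delta_costs.payer_total

    @property
    def delta_societal(self) -> float:
        return self.delta_costs.societal_total

    _ROWS = [
        ("GP (+NS)", "gp_ns"),
        ("Pelvic physiotherapist", "ppt"),
        ("Specialist", "specialist"),
        ("Containment (insured)", "containment_insured"),
        ("UI-related adverse events", "adverse_events"),
        ("Home care", "formal_home_care"),
        ("Implementation costs", "implementation"),
        ("Out-of-pocket costs", None),  # pads out of pocket + travel
        ("Informal care costs", "informal_care"),
    ]

    def to_frame(self) -> pd.DataFrame:
        def col(ar: ArmResult) -> list[float]:
            vals = []
            for _, cat in self._ROWS:
                if cat is None:
                    vals.append(ar.costs.eur["out_of_pocket_containment"]
                                + ar.costs.eur["travel"])
                else:
                    vals.append(ar.costs.eur[cat])
            vals.insert(7, ar.costs.payer_total)   # after implementation row
            vals.append(ar.costs.societal_total)
            vals.append(ar.qalys)
            return vals

        labels = [r[0] for r in self._ROWS]
        labels.insert(7, "Total health care costs")
        labels += ["Total societal costs", "Total QALYs"]
        df = pd.DataFrame({"Usual care": col(self.current), "New care": col(self.new)},
                          index=labels)
        df["Difference"] = df["New care"] - df["Usual care"]
        return df

    def to_json_dict(self) -> dict:
        return {
            "per_arm": {arm: {"costs": getattr(self, arm).costs.eur,
                              "payer_total": getattr(self, arm).costs.payer_total,
                              "societal_total": getattr(self, arm).costs.societal_total,
                              "qalys": getattr(self, arm).qalys}
                        for arm in ("current", "new")},
            "incremental": {"payer": self.delta_payer,
                            "societal": self.delta_societal,
                            "qalys": self.delta_qalys},
        }


def per_patient_results(ps: ParameterSet, prepared: bool = False) -> ResultsTable:
    """Run both arms on the mixed first-year population (prevalent plus
    incident, mass-weighted) and accumulate 3-year per-patient costs and
    QALYs with incrementals."""
    if not prepared:
        ps = prepare(ps)
    pop = target_population(ps)
    n_prev, n_inc = pop["prevalent"], pop["incident_yearly"]
    w_prev = n_prev / (n_prev + n_inc)

    arms = {}
    for arm in ("current", "new"):
        costs = CostVector()
        qalys = 0.0
        outcomes = {}
        for cohort, w in (("prevalent", w_prev), ("incident", 1.0 - w_prev)):
            trace = pw.run_cohort(arm, cohort, ps, prepared=True)
            costs = costs + total_costs(trace, ps).scaled(w)
            qalys += w * total_qalys(trace, ps)
            outcomes[cohort] = pw.outcome_summary(trace)
        arms[arm] = ArmResult(costs=costs, qalys=qalys, outcomes=outcomes)
    return ResultsTable(current=arms["current"], new=arms["new"])
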