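"""Parameter registry for the continence-care decision model.

Every scalar the model consumes lives in a :class:`ParameterSet`: population
counts, the care-pathway transition probabilities for both strategies
(current GP-led care and new nurse-specialist-led care), adverse-event and
care-use rates, unit costs (2013 euros) and health-state utilities.  The
shipped base case (``data/base_case.yaml``) reproduces the published input
tables; :func:`base_case_parameters` returns it with all derived quantities
filled in.

Derived quantities are never stored in config files: per-cycle adverse-event
probabilities, the improvement-state utility (midpoint of the success and
incontinent utilities), the state-dependent formal/informal care costs
(failure-state cost reduced by 10%/25%) and the new-care detection rate
(current detection plus the NS-attributable gain) are recomputed by
:func:`prepare`, so sensitivity analyses that perturb the raw inputs
propagate consistently.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator

import yaml

ARMS = ("current", "new")

#: domains: probability | rate-per-year | cost-eur | utility | count | fraction
#: psa:     beta | uniform | fixed | linked (recomputed from sampled inputs)
_P = ("probability", "beta")
_C = ("cost-eur", "uniform")
_F = ("fraction", "beta")
_N = ("count", "fixed")
_X = ("probability", "fixed")

#: metadata per parameter name: (block, domain, psa distribution, source tag)
REGISTRY: dict[str, tuple[str, str, str, str]] = {}


def _reg(block: str, names: dict[str, tuple[tuple[str, str], str]]) -> None:
    for name, ((domain, psa), source) in names.items():
        REGISTRY[name] = (block, domain, psa, source)


_reg("population", {
    "n_community_elderly": (_N, "national statistics"),
    "multimorbid_share": (("fraction", "fixed"), "primary-care registry"),
    "n_eligible": (_N, "national statistics"),
    "ui_incidence_yearly": (_X, "primary-care registry"),
    "ui_prevalence": (_X, "survey"),
    "n_prevalent": (_N, "derived from survey"),
    "prevalent_female_share": (("fraction", "fixed"), "national statistics"),
})
_reg("settings", {
    "cycle_length_years": (("fraction", "fixed"), "model structure"),
    "horizon_cycles": (_N, "model structure"),
    "warmup_cycles": (_N, "model structure"),
    "implementation_share": (("fraction", "fixed"), "implementation costing"),
    "discount_rate": (("fraction", "fixed"), "assumption"),
    "nursing_home_exit_yearly": (_X, "assumption"),
    "use_rounded_uti": (("fraction", "fixed"), "model structure"),
})
_reg("pathway_current", {
    "detection_incident": (_P, "awareness study"),
    "assess_gp": (_P, "assumption"),
    "assess_ppt": (_P, "assumption"),
    "strategy_cure": (_P, "difference"),
    "strategy_containment": (_P, "expert opinion"),
    "strategy_self": (_P, "assumption"),
    "gp_immediate_referral": (_P, "expert opinion"),
    "gp_referral_to_ppt": (_P, "expert opinion"),
    "gp_referral_to_specialist": (_P, "expert opinion"),
    "gp_rx_medication": (_P, "expert opinion"),
    "gp_medication_improvement": (_P, "trial literature"),
    "gp_medication_success": (_P, "trial literature"),
    "gp_rx_lifestyle": (_P, "expert opinion"),
    "gp_lifestyle_improvement": (_P, "assumption"),
    "gp_lifestyle_success": (_P, "assumption"),
    "gp_rx_uti": (_P, "expert opinion"),
    "gp_uti_improvement": (_P, "assumption"),
    "gp_uti_success": (_P, "assumption"),
    "gp_rx_training": (_P, "expert opinion"),
    "gp_training_improvement": (_P, "expert opinion"),
    "gp_training_success": (_P, "expert opinion"),
    "medication_second_cycle": (_P, "persistence literature"),
    "medication_continue_improvement": (_P, "trial literature"),
    "medication_continue_success": (_P, "trial literature"),
    "ppt_rx_pfmt": (_P, "expert opinion"),
    "ppt_pfmt_improvement": (_P, "expert opinion"),
    "ppt_pfmt_success": (_P, "expert opinion"),
    "ppt_rx_biofeedback": (_P, "expert opinion"),
    "ppt_biofeedback_improvement": (_P, "trial literature"),
    "ppt_biofeedback_success": (_P, "trial literature"),
    "training_continue": (_P, "assumption"),
    "training_second_improvement": (_P, "trial literature"),
    "training_second_success": (_P, "trial literature"),
    "ppt_failure_referral": (_P, "assumption"),
    "ppt_referral_to_gp": (_P, "expert opinion"),
    "ppt_referral_to_specialist": (_P, "expert opinion"),
    "specialist_to_ppt": (_P, "expert opinion"),
    "specialist_treat": (_P, "difference"),
    "specialist_rx_surgery": (_P, "expert opinion"),
    "specialist_surgery_improvement": (_P, "expert opinion"),
    "specialist_surgery_success": (_P, "trial literature"),
    "specialist_rx_conservative": (_P, "expert opinion"),
    "specialist_conservative_improvement": (_P, "trial literature"),
    "specialist_conservative_success": (_P, "assumption"),
    "specialist_rx_medication": (_P, "expert opinion"),
    "specialist_medication_improvement": (_P, "trial literature"),
    "specialist_medication_success": (_P, "guideline"),
    "specialist_failure_referral": (_P, "assumption"),
    "specialist_referral_to_gp": (_P, "assumption"),
    "specialist_referral_to_ppt": (_P, "difference"),
    "prevalent_cure_gp": (_P, "assumption"),
    "prevalent_cure_ppt": (_P, "assumption"),
    "prevalent_cure_specialist": (_P, "assumption"),
})
_reg("pathway_new", {
    "ns_detection_gain": (_P, "awareness study"),
    "extra_detection": (_P, "awareness study"),
    "ns_initial_share": (_P, "difference"),
    "ns_initial_improvement": (_P, "trial literature"),
    "ns_initial_success": (_P, "trial literature"),
    "ns_rx_uti": (_P, "expert opinion"),
    "ns_uti_improvement": (_P, "assumption"),
    "ns_uti_success": (_P, "assumption"),
    "ns_failure_continue": (_P, "assumption"),
    "ns_rx_medication": (_P, "expert opinion"),
    "ns_medication_improvement": (_P, "trial literature"),
    "ns_medication_success": (_P, "trial literature"),
    "ns_medication_second_cycle": (_P, "persistence literature"),
    "ns_medication_continue_improvement": (_P, "trial literature"),
    "ns_medication_continue_success": (_P, "trial literature"),
    "ns_failure_referral": (_P, "assumption"),
    "ns_referral_to_ppt": (_P, "assumption"),
    "ns_referral_to_specialist": (_P, "assumption"),
    # switch: NS delivers the GP first-line package (consults at NS tariff)
    "ns_first_line": (("fraction", "fixed"), "structural switch"),
})
_reg("adverse_events", {
    "uti_yearly_oab": (("rate-per-year", "beta"), "claims literature"),
    "uti_yearly_background": (("rate-per-year", "beta"), "claims literature"),
    "fall_per_cycle": (_P, "cohort literature"),
    "fracture_given_fall": (_P, "injury literature"),
    "skin_per_cycle": (_P, "claims literature"),
})
_reg("care_use", {
    "informal_care_share": (_F, "survey literature"),
    "formal_care_share": (_F, "survey literature"),
    "care_reduction_improvement": (_F, "assumption"),
    "care_reduction_success": (_F, "assumption"),
})
_reg("costs", {
    "consult_gp": (_C, "costing manual"),
    "consult_ns": (_C, "pro-rated salary"),
    "medication_gp_ns": (_C, "tariff"),
    "lifestyle_gp": (_C, "costing manual"),
    "training_gp": (_C, "costing manual"),
    "uti_treatment_gp_ns": (_C, "tariff"),
    "consult_ppt": (_C, "costing manual"),
    "pfmt_ppt": (_C, "expert opinion"),
    "biofeedback_ppt": (_C, "expert opinion"),
    "consult_specialist": (_C, "tariff"),
    "surgery_specialist": (_C, "tariff"),
    "medication_specialist": (_C, "tariff"),
    "conservative_specialist": (_C, "tariff"),
    "pads_success": (("cost-eur", "fixed"), "reimbursement price"),
    "pads_improvement": (_C, "reimbursement price"),
    "pads_failure": (_C, "reimbursement price"),
    "uti_event": (_C, "costing manual"),
    "fracture_event": (_C, "injury costing"),
    "skin_event": (_C, "market price"),
    "formal_care_failure": (_C, "home-care costing"),
    "travel_gp_ns": (_C, "costing manual"),
    "travel_ppt": (_C, "costing manual"),
    "travel_specialist": (_C, "costing manual"),
    "informal_care_failure": (_C, "costing manual"),
    "oop_pads": (_C, "reimbursement price"),
    "implementation_annual": (_C, "implementation costing"),
    "ns_monthly_salary": (("cost-eur", "fixed"), "salary scale"),
    "ns_workable_hours_yearly": (("count", "fixed"), "salary scale"),
})
_reg("utilities", {
    "utility_success": (("utility", "linked"), "EQ-5D survey"),
    "utility_incontinent": (("utility", "beta"), "EQ-5D survey"),
})

#: names created by :func:`prepare`; excluded from round-trips and sampling
DERIVED_NAMES = {
    "uti_excess_yearly", "uti_per_cycle", "fracture_per_cycle",
    "utility_improvement", "formal_care_improvement", "formal_care_success",
    "informal_care_improvement", "informal_care_success",
    "ns_annual_salary", "ns_hourly_wage", "detection_incident@new",
}

#: branch groups that must partition to 1.  The LAST member of each group is
#: the residual branch (the one the source tables tag "Difference" or the
#: natural complement): when the others are sampled or perturbed it absorbs
#: the change as 1 − sum.  scope "new" groups resolve names with fallback to
#: the current-care block.
PARTITION_GROUPS: list[tuple[str, tuple[str, ...]]] = [
    ("current", ("assess_ppt", "assess_gp")),
    ("current", ("strategy_containment", "strategy_self", "strategy_cure")),
    ("current", ("gp_rx_medication", "gp_rx_lifestyle", "gp_rx_uti", "gp_rx_training")),
    ("current", ("gp_referral_to_ppt", "gp_referral_to_specialist")),
    ("current", ("ppt_rx_biofeedback", "ppt_rx_pfmt")),
    ("current", ("ppt_referral_to_gp", "ppt_referral_to_specialist")),
    ("current", ("specialist_to_ppt", "specialist_treat")),
    ("current", ("specialist_rx_surgery", "specialist_rx_conservative", "specialist_rx_medication")),
    ("current", ("specialist_referral_to_ppt", "specialist_referral_to_gp")),
    ("current", ("training_second_improvement", "training_second_success")),
    ("current", ("medication_continue_improvement", "medication_continue_success")),
    ("current", ("prevalent_cure_gp", "prevalent_cure_ppt", "prevalent_cure_specialist")),
    ("new", ("strategy_containment", "strategy_self", "strategy_cure")),
    ("new", ("ns_rx_uti", "ns_initial_share")),
    ("new", ("ns_referral_to_ppt", "ns_referral_to_specialist")),
    ("new", ("ns_medication_continue_improvement", "ns_medication_continue_success")),
    ("new", ("training_second_improvement", "training_second_success")),
]

#: groups rescaled by their sum when sampled instead of using a residual
#: branch: the GP treatment mix is a full expert enumeration whose nominal
#: residual (training) is a zero branch, so a 1−sum residual would be
#: negative in half of all draws
SUM_NORMALISED_GROUPS = {
    ("current", ("gp_rx_medication", "gp_rx_lifestyle", "gp_rx_uti", "gp_rx_training")),
}

#: residual branches: computed as complements during sampling
RESIDUAL_NAMES = {(scope, names[-1]) for scope, names in PARTITION_GROUPS
                  if (scope, names) not in SUM_NORMALISED_GROUPS}

#: (improvement, success) outcome pairs; sum must stay <= 1
OUTCOME_PAIRS: list[tuple[str, tuple[str, str]]] = [
    ("current", ("gp_medication_improvement", "gp_medication_success")),
    ("current", ("gp_lifestyle_improvement", "gp_lifestyle_success")),
    ("current", ("gp_uti_improvement", "gp_uti_success")),
    ("current", ("gp_training_improvement", "gp_training_success")),
    ("current", ("ppt_pfmt_improvement", "ppt_pfmt_success")),
    ("current", ("ppt_biofeedback_improvement", "ppt_biofeedback_success")),
    ("current", ("specialist_surgery_improvement", "specialist_surgery_success")),
    ("current", ("specialist_conservative_improvement", "specialist_conservative_success")),
    ("current", ("specialist_medication_improvement", "specialist_medication_success")),
    ("new", ("ns_initial_improvement", "ns_initial_success")),
    ("new", ("ns_uti_improvement", "ns_uti_success")),
    ("new", ("ns_medication_improvement", "ns_medication_success")),
    ("new", ("ppt_pfmt_improvement", "ppt_pfmt_success")),
]

BRANCH_TOL = 0.01


@dataclass
class ParameterValue:
    name: str
    value: float
    domain: str
    psa_distribution: str = "fixed"
    source_tag: str = ""


class IncompleteParameterSet(KeyError):
    """A name required by the pathway engine is missing."""


@dataclass
class ParameterSet:
    """Shared scalars plus per-arm pathway blocks with new→current fallback."""

    shared: dict[str, ParameterValue] = field(default_factory=dict)
    current: dict[str, ParameterValue] = field(default_factory=dict)
    new: dict[str, ParameterValue] = field(default_factory=dict)

    # -- access ------------------------------------------------------------
    def get(self, name: str, arm: str | None = None) -> float:
        return self.entry(name, arm).value

    def entry(self, name: str, arm: str | None = None) -> ParameterValue:
        if arm == "new":
            if name in self.new:
                return self.new[name]
            if name in self.current:
                return self.current[name]
        elif arm == "current":
            if name in self.current:
                return self.current[name]
        elif arm is None:
            for block in (self.shared, self.current, self.new):
                if name in block:
                    return block[name]
        if name in self.shared:
            return self.shared[name]
        raise IncompleteParameterSet(f"parameter {name!r} (arm={arm}) not in set")

    def has(self, name: str, arm: str | None = None) -> bool:
        try:
            self.entry(name, arm)
            return True
        except KeyError:
            return False

    def set_value(self, name: str, value: float, arm: str | None = None) -> None:
        """Overwrite in place; for arm='new' a fallback entry is copied up."""
        block = {None: self.shared, "current": self.current, "new": self.new}[arm]
        if name not in block:
            proto = self.entry(name, arm)
            block[name] = ParameterValue(name, value, proto.domain,
                                         proto.psa_distribution, proto.source_tag)
        else:
            block[name].value = value

    def copy(self) -> "ParameterSet":
        return ParameterSet(copy.deepcopy(self.shared), copy.deepcopy(self.current),
                            copy.deepcopy(self.new))

    def iter_entries(self) -> Iterator[tuple[str | None, ParameterValue]]:
        for pv in self.shared.values():
            yield None, pv
        for pv in self.current.values():
            yield "current", pv
        for pv in self.new.values():
            yield "new", pv

    # -- config round-trip --------------------------------------------------
    def to_dict(self) -> dict:
        out: dict[str, dict[str, float]] = {}
        for scope, pv in self.iter_entries():
            if pv.name in DERIVED_NAMES or f"{pv.name}@{scope}" in DERIVED_NAMES:
                continue
            if scope == "new":
                block = "pathway_new"
            elif scope == "current":
                block = "pathway_current"
            else:
                block = REGISTRY[pv.name][0]
            out.setdefault(block, {})[pv.name] = pv.value
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, blocks: dict) -> "ParameterSet":
        ps = cls()
        for block, values in blocks.items():
            for name, value in values.items():
                if name not in REGISTRY:
                    raise KeyError(f"unknown parameter {name!r} in block {block!r}")
                _, domain, psa, source = REGISTRY[name]
                pv = ParameterValue(name, float(value), domain, psa, source)
                if block == "pathway_current":
                    ps.current[name] = pv
                elif block == "pathway_new":
                    ps.new[name] = pv
                else:
                    ps.shared[name] = pv
        return ps

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# derivations


def derive_improvement_utility(u_success: float, u_incontinent: float) -> float:
    """Improvement-state utility: midpoint of the success and incontinent
    utilities (the improvement state halves incontinence episodes)."""
    return (u_success + u_incontinent) / 2.0


def derive_cycle_probabilities(ps: ParameterSet) -> ParameterSet:
    """Add the per-cycle adverse-event probabilities.

    The urinary-tract-infection probability per 3-month cycle is the yearly
    excess incidence in the overactive-bladder population over background,
    divided by the 4 cycles of a year (display value 8%; the unrounded
    7.575% is used in computation unless ``use_rounded_uti`` is set).  The
    fracture probability per cycle is the incontinence-attributable fall
    probability times the fracture-given-fall probability.
    """
    ps = ps.copy()
    oab = ps.get("uti_yearly_oab")
    bg = ps.get("uti_yearly_background")
    if oab > 1 or bg > 1:
        raise ValueError("yearly UTI rates must not exceed 1")
    excess = max(oab - bg, 0.0)
    per_cycle = 0.08 if ps.get("use_rounded_uti") else excess / 4.0
    fracture = ps.get("fall_per_cycle") * ps.get("fracture_given_fall")
    for name, value in [("uti_excess_yearly", excess), ("uti_per_cycle", per_cycle),
                        ("fracture_per_cycle", fracture)]:
        ps.shared[name] = ParameterValue(name, value, "probability", "fixed", "derived")
    return ps


def prepare(ps: ParameterSet) -> ParameterSet:
    """Return a copy with every derived quantity filled in."""
    ps = derive_cycle_probabilities(ps)

    u_imp = derive_improvement_utility(ps.get("utility_success"),
                                       ps.get("utility_incontinent"))
    ps.shared["utility_improvement"] = ParameterValue(
        "utility_improvement", u_imp, "utility", "linked", "derived")

    red_i = ps.get("care_reduction_improvement")
    red_s = ps.get("care_reduction_success")
    for kind in ("formal_care", "informal_care"):
        fail = ps.get(f"{kind}_failure")
        ps.shared[f"{kind}_improvement"] = ParameterValue(
            f"{kind}_improvement", fail * (1 - red_i), "cost-eur", "linked", "derived")
        ps.shared[f"{kind}_success"] = ParameterValue(
            f"{kind}_success", fail * (1 - red_s), "cost-eur", "linked", "derived")

    salary = ps.get("ns_monthly_salary") * 12.0
    ps.shared["ns_annual_salary"] = ParameterValue(
        "ns_annual_salary", salary, "cost-eur", "fixed", "derived")
    ps.shared["ns_hourly_wage"] = ParameterValue(
        "ns_hourly_wage", salary / ps.get("ns_workable_hours_yearly"),
        "cost-eur", "fixed", "derived")

    det = min(ps.get("detection_incident", "current") + ps.get("ns_detection_gain", "new"), 1.0)
    ps.new["detection_incident"] = ParameterValue(
        "detection_incident", det, "probability", "linked", "derived")
    return ps


def base_case_parameters() -> ParameterSet:
    """The published base case with all derived quantities filled in."""
    path = resources.files("continence_ce").joinpath("data/base_case.yaml")
    with resources.as_file(path) as p:
        return prepare(ParameterSet.from_yaml(p))


# ---------------------------------------------------------------------------
# validation

#: names the pathway engine dereferences; absence is an "incomplete set" error
REQUIRED_NAMES: dict[str, tuple[str, ...]] = {
    "current": (
        "detection_incident", "assess_gp", "assess_ppt", "strategy_cure",
        "strategy_containment", "strategy_self", "gp_immediate_referral",
        "gp_referral_to_ppt", "gp_referral_to_specialist", "gp_rx_medication",
        "gp_rx_lifestyle", "gp_rx_uti", "gp_rx_training",
        "gp_medication_improvement", "gp_medication_success",
        "medication_second_cycle", "medication_continue_improvement",
        "medication_continue_success", "ppt_rx_pfmt", "ppt_pfmt_improvement",
        "ppt_rx_biofeedback", "ppt_biofeedback_improvement",
        "ppt_biofeedback_success", "training_second_improvement",
        "training_second_success", "ppt_referral_to_gp",
        "ppt_referral_to_specialist", "specialist_to_ppt", "specialist_treat",
        "specialist_rx_surgery", "specialist_rx_medication",
        "prevalent_cure_gp", "prevalent_cure_ppt", "prevalent_cure_specialist",
    ),
    "new": (
        "detection_incident", "extra_detection", "strategy_cure",
        "ns_initial_share", "ns_initial_improvement", "ns_initial_success",
        "ns_failure_continue", "ns_failure_referral", "ns_referral_to_ppt",
        "ns_referral_to_specialist", "ns_medication_improvement",
        "ns_medication_success",
    ),
}


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:  # plain-text view
        if self.ok:
            return "parameter set valid: no violations"
        return "\n".join(f"- {v}" for v in self.violations)

    def to_json(self) -> dict:
        return {"ok": self.ok, "violations": list(self.violations)}


def validate_parameter_set(ps: ParameterSet) -> ValidationReport:
    """Check domains, branch-group closure, utility ordering, completeness."""
    rep = ValidationReport()
    ps = prepare(ps)

    for scope, pv in ps.iter_entries():
        tag = pv.name if scope is None else f"{pv.name}[{scope}]"
        if pv.domain in ("probability", "utility", "fraction"):
            if not (0.0 <= pv.value <= 1.0):
                rep.violations.append(f"{pv.domain} out of [0,1]: {tag} = {pv.value}")
        elif pv.domain == "cost-eur":
            if pv.value < 0:
                rep.violations.append(f"negative cost: {tag} = {pv.value}")
        elif pv.domain == "count":
            if pv.value < 0 or pv.value != int(pv.value):
                rep.violations.append(f"count not a non-negative integer: {tag} = {pv.value}")

    for scope, names in PARTITION_GROUPS:
        try:
            total = sum(ps.get(n, scope) for n in names)
        except IncompleteParameterSet:
            continue  # reported by the completeness check below
        if not math.isclose(total, 1.0, abs_tol=BRANCH_TOL):
            rep.violations.append(
                f"branch sum != 1 ({scope}): {'+'.join(names)} = {total:.4f}")
    for scope, (imp, succ) in OUTCOME_PAIRS:
        try:
            total = ps.get(imp, scope) + ps.get(succ, scope)
        except IncompleteParameterSet:
            continue
        if total > 1.0 + BRANCH_TOL:
            rep.violations.append(
                f"improvement+success > 1 ({scope}): {imp}+{succ} = {total:.4f}")

    try:
        u_s, u_i = ps.get("utility_success"), ps.get("utility_incontinent")
        u_m = ps.get("utility_improvement")
        if not (u_i <= u_m <= u_s):
            rep.violations.append(
                f"utility ordering violated: {u_i} <= {u_m} <= {u_s} fails")
    except IncompleteParameterSet:
        pass

    for arm, names in REQUIRED_NAMES.items():
        for name in names:
            if not ps.has(name, arm):
                rep.violations.append(f"incomplete set: missing {name!r} for arm {arm!r}")
    return rep


def apply_residual_complements(ps: ParameterSet) -> ParameterSet:
    """Set each group's residual branch to 1 − sum(sampled branches).

    When the sampled branches already exceed 1 they are scaled down and the
    residual becomes 0.  Outcome pairs exceeding 1 are scaled.  Modifies in
    place and returns the set.
    """
    for scope, names in PARTITION_GROUPS:
        try:
            if (scope, names) in SUM_NORMALISED_GROUPS:
                total = sum(ps.get(n, scope) for n in names)
                if total > 0:
                    for n in names:
                        ps.set_value(n, ps.get(n, scope) / total, arm=scope)
                continue
            others = sum(ps.get(n, scope) for n in names[:-1])
        except IncompleteParameterSet:
            continue
        if others <= 1.0:
            ps.set_value(names[-1], 1.0 - others, arm=scope)
        else:
            for n in names[:-1]:
                ps.set_value(n, ps.get(n, scope) / others, arm=scope)
            ps.set_value(names[-1], 0.0, arm=scope)
    for scope, (imp, succ) in OUTCOME_PAIRS:
        try:
            total = ps.get(imp, scope) + ps.get(succ, scope)
        except IncompleteParameterSet:
            continue
        if total > 1.0:
            ps.set_value(imp, ps.get(imp, scope) / total, arm=scope)
            ps.set_value(succ, ps.get(succ, scope) / total, arm=scope)
    return ps


def renormalise_groups(ps: ParameterSet) -> ParameterSet:
    """Rescale branch groups to sum to one and cap outcome pairs at one.

    Used after perturbing or sampling raw parameters; mean-preserving within
    each group (every member divided by the group sum).  Modifies in place
    and returns the set.
    """
    for scope, names in PARTITION_GROUPS:
        try:
            total = sum(ps.get(n, scope) for n in names)
        except IncompleteParameterSet:
            continue
        if total > 0 and not math.isclose(total, 1.0, abs_tol=1e-12):
            for n in names:
                ps.set_value(n, ps.get(n, scope) / total, arm=scope)
    for scope, (imp, succ) in OUTCOME_PAIRS:
        try:
            total = ps.get(imp, scope) + ps.get(succ, scope)
        except IncompleteParameterSet:
            continue
        if total > 1.0:
            ps.set_value(imp, ps.get(imp, scope) / total, arm=scope)
            ps.set_value(succ, ps.get(succ, scope) / total, arm=scope)
    return ps


# ---------------------------------------------------------------------------
# population arithmetic


def target_population(ps: ParameterSet) -> dict[str, int]:
    """Target-population counts.

    The eligible population count is taken as printed (the 31% multimorbidity
    share is a rounded display of age–sex-stratified shares and is not used
    for arithmetic).  Yearly detected incident cases are eligible population
    times yearly incidence, rounded down; the prevalent count and its sex
    split are printed inputs.
    """
    eligible = int(ps.get("n_eligible"))
    incident = math.floor(eligible * ps.get("ui_incidence_yearly"))
    prevalent = int(ps.get("n_prevalent"))
    women = round(prevalent * ps.get("prevalent_female_share"))
    return {
        "eligible": eligible,
        "incident_yearly": incident,
        "prevalent": prevalent,
        "prevalent_women": women,
        "prevalent_men": prevalent - women,
    }
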