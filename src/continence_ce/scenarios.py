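"""Scenario analyses and ICER computation.

Three scenarios, each a pure parameter transform re-run through the same
per-patient pipeline:

``full_implementation``
    the full national implementation cost is carried by this target
    population instead of its base-case share (23.8%);
``detection_only``
    new care raises detection (incident detection gain and prevalent extra
    detection retained) but the NS delivers the GP pathway's treatment mix
    and effectiveness; NS consultations still occur and are costed;
``effectiveness_only``
    new care keeps the NS treatment pathway but detection equals current
    care (no detection gain, no extra prevalent detection, no re-engagement
    of self-managers).
"""

from __future__ import annotations

from dataclasses import dataclass

from .economics import ResultsTable, per_patient_results
from .params import ParameterSet

SCENARIOS = ("full_implementation", "detection_only", "effectiveness_only")


def scenario_parameters(name: str, ps: ParameterSet) -> ParameterSet:
    """Return the transformed parameter set for a named scenario."""
    ps = ps.copy()
    if name == "full_implementation":
        ps.set_value("implementation_share", 1.0)
    elif name == "detection_only":
        # the NS still assesses, consults and allocates (all costed), but
        # every treatment outcome takes the corresponding GP-pathway
        # probability: the NS training/lifestyle package performs like GP
        # lifestyle advice, her UTI and medication branches like the GP's,
        # and the downstream PPT parameters revert to current care
        for target, source in (("ns_initial_improvement", "gp_lifestyle_improvement"),
                               ("ns_initial_success", "gp_lifestyle_success"),
                               ("ns_uti_improvement", "gp_uti_improvement"),
                               ("ns_uti_success", "gp_uti_success"),
                               ("ns_medication_improvement", "gp_medication_improvement"),
                               ("ns_medication_success", "gp_medication_success"),
                               ("ns_medication_second_cycle", "medication_second_cycle"),
                               ("ns_medication_continue_improvement", "medication_continue_improvement"),
                               ("ns_medication_continue_success", "medication_continue_success")):
            ps.set_value(target, ps.get(source, "current"), arm="new")
        for override in ("ppt_pfmt_improvement", "training_second_improvement",
                         "training_second_success"):
            ps.new.pop(override, None)  # fall back to current-care values
    elif name == "effectiveness_only":
        ps.set_value("ns_detection_gain", 0.0, arm="new")
        ps.set_value("extra_detection", 0.0, arm="new")
    else:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    return ps


def run_scenario(name: str, ps: ParameterSet) -> ResultsTable:
    return per_patient_results(scenario_parameters(name, ps))


@dataclass
class IcerResult:
    delta_cost: float
    delta_qaly: float
    classification: str  # dominant | dominated | icer-defined | equivalent
    icer: float | None = None


def icer(delta_cost: float, delta_qaly: float) -> IcerResult:
    """Incremental cost-effectiveness ratio with dominance classification.

    Dominant: cheaper and at least as effective (not both deltas zero);
    dominated: the mirror image; otherwise the ratio is reported whenever
    the QALY difference is nonzero.
    """
    if delta_cost == 0.0 and delta_qaly == 0.0:
        return IcerResult(delta_cost, delta_qaly, "equivalent")
    if delta_cost <= 0.0 and delta_qaly >= 0.0:
        return IcerResult(delta_cost, delta_qaly, "dominant")
    if delta_cost >= 0.0 and delta_qaly <= 0.0:
        return IcerResult(delta_cost, delta_qaly, "dominated")
    return IcerResult(delta_cost, delta_qaly, "icer-defined",
                      icer=delta_cost / delta_qaly)
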