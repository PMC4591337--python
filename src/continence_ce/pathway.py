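"""Decision tree and Markov cure pathway for the two care strategies.

The cohort is propagated as mass fractions over compound states
(lane × provider × treatment phase × health state).  Entry goes through the
detection / assessment / strategy decision tree; patients treated for cure
flow through provider lanes (GP or nurse specialist first line, pelvic
physiotherapist, specialist) with referral loops, explicit medication and
training continuation rules, and three health states: incontinent,
improvement (≥50% fewer episodes) and success (continent, absorbing).

Conventions
-----------
* A treatment attempt occupies exactly one cycle; an immediate referral is
  resolved within the same cycle at the receiving provider (its consultation
  is booked there).
* Failures who are not referred onward stop active treatment and keep
  insured containment (``CONT_X``).
* Improvement converts to success only through explicit continuation rules
  (second medication cycle, second training cycle); when treatment ends,
  improved patients stay improved (``IMP_IN``).
* Outcomes materialise at the end of the cycle: the trace distribution at
  index ``t`` is the state *after* cycle ``t``'s treatments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import ParameterSet, prepare

MASS_TOL = 1e-9

# compound states ------------------------------------------------------------
UNDET = "undetected"            # never detected, incontinent (absorbing)
CONT = "containment"            # containment only, insured pads
CONT_X = "containment_post"     # stopped active treatment after failure
SELF = "self_management"        # out-of-pocket pads, incontinent
SUCC = "success"                # continent (absorbing, exits active pathway)
IMP_IN = "improved_inactive"    # improvement, no further treatment
IMP_MED_GP = "improved_med_gp"  # improvement on GP medication, may continue
IMP_MED_SPEC = "improved_med_specialist"
IMP_MED_NS = "improved_med_ns"
IMP_TRAIN = "improved_training"  # improvement after PFMT, second cycle follows
PEND_GP = "pending_gp"          # awaiting a GP treatment attempt this cycle
PEND_PPT = "pending_ppt"
PEND_SPEC = "pending_specialist"
PEND_NS = "pending_ns"          # awaiting the initial NS package (new care)
PEND_NS_MED = "pending_ns_med"  # NS failures continuing with NS medication

STATES = (UNDET, CONT, CONT_X, SELF, SUCC, IMP_IN, IMP_MED_GP, IMP_MED_SPEC,
          IMP_MED_NS, IMP_TRAIN, PEND_GP, PEND_PPT, PEND_SPEC, PEND_NS,
          PEND_NS_MED)

IMPROVED_STATES = (IMP_IN, IMP_MED_GP, IMP_MED_SPEC, IMP_MED_NS, IMP_TRAIN)
ACTIVE_CURE_STATES = (PEND_GP, PEND_PPT, PEND_SPEC, PEND_NS, PEND_NS_MED)
#: detected lanes whose pads are reimbursed by the insurer
INSURED_FAILURE_STATES = (CONT, CONT_X) + ACTIVE_CURE_STATES

#: consultation / treatment events booked per cycle (unit: patient-events)
EVENTS = ("gp_consult", "ns_consult", "ppt_consult", "specialist_consult",
          "med_gp_ns", "lifestyle", "training_gp", "uti_rx", "pfmt",
          "biofeedback", "surgery", "med_specialist", "conservative")


def zero_vec() -> dict[str, float]:
    return dict.fromkeys(STATES, 0.0)


def zero_events() -> dict[str, float]:
    return dict.fromkeys(EVENTS, 0.0)


class _Arm:
    """Attribute-style parameter access for one arm with fallback."""

    __slots__ = ("ps", "arm")

    def __init__(self, ps: ParameterSet, arm: str):
        self.ps, self.arm = ps, arm

    def __call__(self, name: str) -> float:
        return self.ps.get(name, self.arm)

    def get(self, name: str, default: float) -> float:
        return self.ps.get(name, self.arm) if self.ps.has(name, self.arm) else default


@dataclass
class StrategyAllocation:
    undetected: float
    cure: float
    containment_only: float
    self_management: float
    #: provider split of the cure mass (keys: gp, ppt, specialist, ns)
    cure_providers: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {"undetected": self.undetected, "cure": self.cure,
                "containment_only": self.containment_only,
                "self_management": self.self_management}

    def check(self) -> None:
        total = sum(self.as_dict().values())
        if abs(total - 1.0) > 1e-9 or min(self.as_dict().values()) < -1e-12:
            raise ValueError(f"invalid strategy allocation (sum {total})")


@dataclass
class CohortTrace:
    arm: str
    cohort: str
    vecs: list[dict[str, float]]            # index 0 = initial allocation
    events: list[dict[str, float]]          # events[t] booked during cycle t+1

    @property
    def horizon(self) -> int:
        return len(self.vecs) - 1

    def occupancy(self, t: int) -> tuple[float, float, float]:
        """(incontinent, improved, success) health-state mass after cycle t."""
        v = self.vecs[t]
        succ = v[SUCC]
        imp = sum(v[s] for s in IMPROVED_STATES)
        return 1.0 - succ - imp, imp, succ

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.vecs).rename_axis("cycle")


@dataclass
class OutcomeSummary:
    pct_success: float
    pct_improved: float
    pct_not_improved: float


# ---------------------------------------------------------------------------
# within-cycle treatment resolution
#
# Each _treat_* helper distributes a mass of patients treated this cycle over
# next-cycle states, booking consultation/treatment events.  Immediate
# referrals recurse into the receiving provider within the same cycle.


def _treat_ppt(m: float, nxt: dict, ev: dict, P: _Arm) -> None:
    if m <= 0.0:
        return
    ev["ppt_consult"] += m
    pfmt = m * P("ppt_rx_pfmt")
    bio = m * P("ppt_rx_biofeedback")
    ev["pfmt"] += pfmt
    ev["biofeedback"] += bio
    imp = pfmt * P("ppt_pfmt_improvement") + bio * P("ppt_biofeedback_improvement")
    succ = pfmt * P("ppt_pfmt_success") + bio * P("ppt_biofeedback_success")
    nxt[IMP_TRAIN] += imp
    nxt[SUCC] += succ
    fail = m - imp - succ
    ref = fail * P("ppt_failure_referral")
    nxt[PEND_GP] += ref * P("ppt_referral_to_gp")
    nxt[PEND_SPEC] += ref * P("ppt_referral_to_specialist")
    nxt[CONT_X] += fail - ref


def _treat_spec(m: float, nxt: dict, ev: dict, P: _Arm) -> None:
    if m <= 0.0:
        return
    _treat_ppt(m * P("specialist_to_ppt"), nxt, ev, P)
    t = m * P("specialist_treat")
    if t <= 0.0:
        return
    ev["specialist_consult"] += t
    surg = t * P("specialist_rx_surgery")
    cons = t * P("specialist_rx_conservative")
    med = t * P("specialist_rx_medication")
    ev["surgery"] += surg
    ev["conservative"] += cons
    ev["med_specialist"] += med
    nxt[IMP_IN] += (surg * P("specialist_surgery_improvement")
                    + cons * P("specialist_conservative_improvement"))
    nxt[IMP_MED_SPEC] += med * P("specialist_medication_improvement")
    succ = (surg * P("specialist_surgery_success")
            + cons * P("specialist_conservative_success")
            + med * P("specialist_medication_success"))
    nxt[SUCC] += succ
    fail = (surg * (1 - P("specialist_surgery_improvement") - P("specialist_surgery_success"))
            + cons * (1 - P("specialist_conservative_improvement") - P("specialist_conservative_success"))
            + med * (1 - P("specialist_medication_improvement") - P("specialist_medication_success")))
    ref = fail * P("specialist_failure_referral")
    nxt[PEND_GP] += ref * P("specialist_referral_to_gp")
    nxt[PEND_PPT] += ref * P("specialist_referral_to_ppt")
    nxt[CONT_X] += fail - ref


def _treat_gp(m: float, nxt: dict, ev: dict, P: _Arm, consult_key: str = "gp_consult") -> None:
    """GP decision node: immediate referral or a first-line treatment attempt.

    ``consult_key`` lets a nurse specialist deliver the identical first-line
    package (consultations costed at the NS tariff)."""
    if m <= 0.0:
        return
    ev[consult_key] += m
    ref = m * P("gp_immediate_referral")
    _treat_ppt(ref * P("gp_referral_to_ppt"), nxt, ev, P)
    _treat_spec(ref * P("gp_referral_to_specialist"), nxt, ev, P)
    att = m - ref
    if att <= 0.0:
        return
    med = att * P("gp_rx_medication")
    life = att * P("gp_rx_lifestyle")
    uti = att * P("gp_rx_uti")
    train = att * P("gp_rx_training")
    ev["med_gp_ns"] += med
    ev["lifestyle"] += life
    ev["uti_rx"] += uti
    ev["training_gp"] += train
    nxt[IMP_MED_GP] += med * P("gp_medication_improvement")
    nxt[IMP_IN] += (life * P("gp_lifestyle_improvement")
                    + uti * P("gp_uti_improvement")
                    + train * P("gp_training_improvement"))
    succ = (med * P("gp_medication_success") + life * P("gp_lifestyle_success")
            + uti * P("gp_uti_success") + train * P("gp_training_success"))
    nxt[SUCC] += succ
    fail = (med * (1 - P("gp_medication_improvement") - P("gp_medication_success"))
            + life * (1 - P("gp_lifestyle_improvement") - P("gp_lifestyle_success"))
            + uti * (1 - P("gp_uti_improvement") - P("gp_uti_success"))
            + train * (1 - P("gp_training_improvement") - P("gp_training_success")))
    ref2 = fail * P("gp_immediate_referral")
    nxt[PEND_PPT] += ref2 * P("gp_referral_to_ppt")
    nxt[PEND_SPEC] += ref2 * P("gp_referral_to_specialist")
    nxt[CONT_X] += fail - ref2


def _treat_ns(m: float, nxt: dict, ev: dict, P: _Arm) -> None:
    """Initial NS package (new care): three consultations of training and
    lifestyle advice, or treatment of a urinary infection."""
    if m <= 0.0:
        return
    ev["ns_consult"] += 3.0 * m
    init = m * P("ns_initial_share")
    uti = m * P("ns_rx_uti")
    ev["uti_rx"] += uti
    nxt[IMP_IN] += init * P("ns_initial_improvement") + uti * P("ns_uti_improvement")
    nxt[SUCC] += init * P("ns_initial_success") + uti * P("ns_uti_success")
    fail = (init * (1 - P("ns_initial_improvement") - P("ns_initial_success"))
            + uti * (1 - P("ns_uti_improvement") - P("ns_uti_success")))
    cont = fail * P("ns_failure_continue")
    nxt[PEND_NS_MED] += cont * P("ns_rx_medication")
    nxt[CONT_X] += cont * (1 - P("ns_rx_medication"))
    ref = fail - cont
    nxt[PEND_PPT] += ref * P("ns_referral_to_ppt")
    nxt[PEND_SPEC] += ref * P("ns_referral_to_specialist")


def _treat_ns_med(m: float, nxt: dict, ev: dict, P: _Arm) -> None:
    if m <= 0.0:
        return
    ev["ns_consult"] += m
    ev["med_gp_ns"] += m
    nxt[IMP_MED_NS] += m * P("ns_medication_improvement")
    nxt[SUCC] += m * P("ns_medication_success")
    fail = m * (1 - P("ns_medication_improvement") - P("ns_medication_success"))
    ref = fail * P("ns_failure_referral")
    nxt[PEND_PPT] += ref * P("ns_referral_to_ppt")
    nxt[PEND_SPEC] += ref * P("ns_referral_to_specialist")
    nxt[CONT_X] += fail - ref


def _med_continuation(m: float, nxt: dict, ev: dict, P: _Arm,
                      second_cycle: str, imp_key: str, succ_key: str,
                      med_event: str, stay_state: str) -> None:
    """Medication persistence: each cycle a share of improved users continues
    (persistence taken from 9–12-month discontinuation data, so applied per
    cycle, not once); continuing users convert to success or remain improved
    and may continue again; discontinuers keep their improvement."""
    if m <= 0.0:
        return
    cont = m * P(second_cycle)
    ev[med_event] += cont
    nxt[SUCC] += cont * P(succ_key)
    nxt[stay_state] += cont * P(imp_key)
    nxt[IMP_IN] += m - cont


def cure_pathway_step(vec: dict[str, float], cycle: int, arm: str,
                      ps: ParameterSet) -> tuple[dict[str, float], dict[str, float]]:
    """Advance the cohort one cycle; returns (next distribution, events).

    Raises on mass-conservation violations beyond 1e-9.
    """
    P = _Arm(ps, arm)
    nxt = zero_vec()
    ev = zero_events()

    for s in (UNDET, CONT, CONT_X, SELF, SUCC, IMP_IN):
        nxt[s] += vec[s]

    _med_continuation(vec[IMP_MED_GP], nxt, ev, P, "medication_second_cycle",
                      "medication_continue_improvement",
                      "medication_continue_success", "med_gp_ns", IMP_MED_GP)
    _med_continuation(vec[IMP_MED_SPEC], nxt, ev, P, "medication_second_cycle",
                      "medication_continue_improvement",
                      "medication_continue_success", "med_specialist", IMP_MED_SPEC)
    if vec[IMP_MED_NS] > 0.0:
        _med_continuation(vec[IMP_MED_NS], nxt, ev, P, "ns_medication_second_cycle",
                          "ns_medication_continue_improvement",
                          "ns_medication_continue_success", "med_gp_ns", IMP_MED_NS)

    m = vec[IMP_TRAIN]
    if m > 0.0:
        cont = m * P("training_continue")
        ev["ppt_consult"] += cont
        ev["pfmt"] += cont
        nxt[SUCC] += cont * P("training_second_success")
        nxt[IMP_IN] += cont * P("training_second_improvement") + (m - cont)

    ns_first_line = P.get("ns_first_line", 0.0) > 0.0
    _treat_gp(vec[PEND_GP], nxt, ev, P)
    _treat_ppt(vec[PEND_PPT], nxt, ev, P)
    _treat_spec(vec[PEND_SPEC], nxt, ev, P)
    if vec[PEND_NS] > 0.0:
        if ns_first_line:
            # scenario: NS delivers care but with the GP pathway's
            # treatment mix and effectiveness
            _treat_gp(vec[PEND_NS], nxt, ev, P, consult_key="ns_consult")
        else:
            _treat_ns(vec[PEND_NS], nxt, ev, P)
    _treat_ns_med(vec[PEND_NS_MED], nxt, ev, P)

    if abs(sum(nxt.values()) - sum(vec.values())) > MASS_TOL:
        raise ArithmeticError(
            f"mass not conserved in cycle {cycle}: "
            f"{sum(vec.values())} -> {sum(nxt.values())}")
    return nxt, ev


# ---------------------------------------------------------------------------
# cohort entry


def allocate_incident_cohort(arm: str, ps: ParameterSet) -> StrategyAllocation:
    """Decision-tree allocation of a newly presenting cohort."""
    P = _Arm(ps, arm)
    det = P("detection_incident")
    shares = [P("strategy_cure"), P("strategy_containment"), P("strategy_self")]
    total = sum(shares)
    cure, cont, selfm = (s / total for s in shares)
    # new care starts at the NS lane; when the NS delivers the GP package
    # (detection-only scenario) the lane is still entered as NS so the
    # consultations are costed at the NS tariff
    providers = {"gp": 1.0} if arm == "current" else {"ns": 1.0}
    alloc = StrategyAllocation(undetected=1.0 - det, cure=det * cure,
                               containment_only=det * cont,
                               self_management=det * selfm,
                               cure_providers=providers)
    alloc.check()
    return alloc


def _entry_vec(alloc: StrategyAllocation) -> dict[str, float]:
    vec = zero_vec()
    vec[UNDET] = alloc.undetected
    vec[CONT] = alloc.containment_only
    vec[SELF] = alloc.self_management
    lane = {"gp": PEND_GP, "ppt": PEND_PPT, "specialist": PEND_SPEC, "ns": PEND_NS}
    for prov, share in alloc.cure_providers.items():
        vec[lane[prov]] += alloc.cure * share
    return vec


def _assessment_events(arm: str, alloc: StrategyAllocation, ps: ParameterSet,
                       newly_detected: float | None = None) -> dict[str, float]:
    """Initial assessment consultations for the newly detected mass."""
    ev = zero_events()
    P = _Arm(ps, arm)
    detected = (1.0 - alloc.undetected) if newly_detected is None else newly_detected
    if detected <= 0.0:
        return ev
    if arm == "current":
        tot = P("assess_gp") + P("assess_ppt")
        ev["gp_consult"] += detected * P("assess_gp") / tot
        ev["ppt_consult"] += detected * P("assess_ppt") / tot
    else:
        ev["ns_consult"] += detected
    return ev


def run_cohort(arm: str, cohort: str, ps: ParameterSet,
               horizon: int | None = None, prepared: bool = False) -> CohortTrace:
    """Propagate a cohort (``incident`` or ``prevalent``) over the horizon."""
    if not prepared:
        ps = prepare(ps)
    if horizon is None:
        horizon = int(ps.get("horizon_cycles"))
    if cohort == "incident":
        alloc = allocate_incident_cohort(arm, ps)
        vec = _entry_vec(alloc)
        entry_ev = _assessment_events(arm, alloc, ps)
    elif cohort == "prevalent":
        alloc = derive_prevalent_allocation(arm, ps, prepared=True)
        vec = _entry_vec(alloc)
        # under new care the extra detected prevalent mass (and re-engaged
        # self-managers) receive an NS assessment; the rest were assessed
        # long before the model starts
        newly = 0.0
        if arm == "new":
            cur = derive_prevalent_allocation("current", ps, prepared=True)
            newly = min(ps.get("extra_detection", "new"), cur.undetected)
            if newly > 0.0:
                newly += cur.self_management
        entry_ev = _assessment_events(arm, alloc, ps, newly_detected=newly)
    else:
        raise ValueError(f"unknown cohort {cohort!r}")

    vecs = [vec]
    events = []
    for t in range(1, horizon + 1):
        vec, ev = cure_pathway_step(vec, t, arm, ps)
        if t == 1:
            for k, v in entry_ev.items():
                ev[k] += v
        vecs.append(vec)
        events.append(ev)
    return CohortTrace(arm=arm, cohort=cohort, vecs=vecs, events=events)


# ---------------------------------------------------------------------------
# prevalent pool


def derive_prevalent_allocation(arm: str, ps: ParameterSet,
                                prepared: bool = False) -> StrategyAllocation:
    """Distribution of the prevalent pool over the care pathway.

    The current-care incident cohort is run for one year (4 cycles); the
    cumulative success mass leaves the pool and the remainder is
    renormalised.  Improved patients whose treatment has ended rejoin the
    incontinent never-in-care pool (the prevalent cohort starts with no
    retained improvement), non-referred failures keep insured containment,
    and the still-active cure mass is re-spread equally over the GP, PPT and
    specialist lanes.

    Under new care an extra share of the never-detected pool (the
    NS-attributable extra detection) is detected at model start and split
    over cure/containment by the new-care strategy shares, and
    self-managers are re-engaged into treatment for cure.
    """
    if not prepared:
        ps = prepare(ps)
    warm = int(ps.get("warmup_cycles"))
    base = run_cohort("current", "incident", ps, horizon=warm, prepared=True)
    v = base.vecs[-1]
    remaining = 1.0 - v[SUCC]
    undet = (v[UNDET] + sum(v[s] for s in IMPROVED_STATES)) / remaining
    cont = (v[CONT] + v[CONT_X]) / remaining
    selfm = v[SELF] / remaining
    cure = sum(v[s] for s in ACTIVE_CURE_STATES) / remaining

    P = _Arm(ps, "current")
    thirds = [P("prevalent_cure_gp"), P("prevalent_cure_ppt"), P("prevalent_cure_specialist")]
    tot = sum(thirds)
    providers = {"gp": thirds[0] / tot, "ppt": thirds[1] / tot, "specialist": thirds[2] / tot}

    if arm == "current":
        alloc = StrategyAllocation(undet, cure, cont, selfm, providers)
        alloc.check()
        return alloc

    Pn = _Arm(ps, "new")
    extra = min(Pn("extra_detection"), undet)
    if extra <= 0.0:
        # no NS-attributable extra detection: the prevalent pool is
        # unchanged, only the residual cure mass enters through the NS
        alloc = StrategyAllocation(undet, cure, cont, selfm, {"ns": 1.0})
        alloc.check()
        return alloc
    shares = [Pn("strategy_cure"), Pn("strategy_containment")]
    cure_share = shares[0] / (shares[0] + shares[1])
    undet_n = undet - extra
    cure_n = cure + extra * cure_share + selfm  # re-engaged self-managers treated for cure
    cont_n = cont + extra * (1.0 - cure_share)
    # the new-care prevalent cure mass is almost entirely newly detected by
    # the NS (plus re-engaged self-managers), so it enters care through the
    # NS first line rather than the residual GP/PPT/specialist split
    alloc = StrategyAllocation(undet_n, cure_n, cont_n, 0.0, {"ns": 1.0})
    alloc.check()
    return alloc


def outcome_summary(trace: CohortTrace) -> OutcomeSummary:
    fail, imp, succ = trace.occupancy(trace.horizon)
    return OutcomeSummary(pct_success=100.0 * succ, pct_improved=100.0 * imp,
                          pct_not_improved=100.0 * fail)
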