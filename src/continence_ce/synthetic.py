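"""Synthetic inputs and an independent patient-level simulation oracle.

Three generators keep the full pipeline testable without any external data:

* a synthetic life table (Gompertz-shaped yearly death probabilities by
  5-year age band and sex) standing in for national life tables — it is NOT
  observed mortality data, so budget-impact outputs driven by it are
  indicative only;
* randomised-but-valid parameter sets for property-based testing of the
  cohort engine;
* a patient-level microsimulation of the same care pathway that shares only
  the :class:`~continence_ce.params.ParameterSet` with the cohort engine
  (none of its code), used as a Monte-Carlo oracle for the deterministic
  cohort propagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import (DERIVED_NAMES, REGISTRY, ParameterSet, prepare,
                     renormalise_groups)
from .pathway import derive_prevalent_allocation

AGE_BANDS = ("65-69", "70-74", "75-79", "80-84", "85-89", "90-94", "95+")
_BAND_MID = (67.0, 72.0, 77.0, 82.0, 87.0, 92.0, 99.0)
#: age distribution of the multimorbid 65+ pool, skewed old and female
_BAND_WEIGHT = (0.20, 0.21, 0.20, 0.17, 0.12, 0.07, 0.03)
_FEMALE_SHARE = 0.62


def generate_life_table(seed: int = 0, base_q65: float = 0.012,
                        slope: float = 0.095) -> pd.DataFrame:
    """Synthetic yearly death probabilities by age band and sex.

    ``q(age) = base_q65 * exp(slope * (age - 65))`` with a female advantage
    and a small seeded lognormal jitter; deterministic given the seed and
    monotone non-decreasing in age.
    """
    if not (0.0 < base_q65 < 1.0):
        raise ValueError("base_q65 must lie in (0, 1)")
    if slope < 0.0:
        raise ValueError("slope must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for sex, factor in (("male", 1.15), ("female", 0.80)):
        jitter = np.exp(rng.normal(0.0, 0.03, size=len(AGE_BANDS)))
        q = base_q65 * factor * np.exp(slope * (np.array(_BAND_MID) - 65.0)) * jitter
        q = np.minimum.accumulate(np.minimum(q, 0.95)[::-1])[::-1]  # keep monotone
        q = np.maximum.accumulate(q)
        for band, qi in zip(AGE_BANDS, q):
            rows.append({"age_band": band, "sex": sex, "q_yearly": float(qi)})
    return pd.DataFrame(rows)


def generate_demography(seed: int = 0, base_q65: float = 0.012,
                        slope: float = 0.095) -> pd.DataFrame:
    """Demography table for the budget impact: stratum weights and
    cumulative 1/2/3-year death probabilities (q1 <= q2 <= q3)."""
    lt = generate_life_table(seed, base_q65, slope)
    rows = []
    for (band, sex), grp in lt.groupby(["age_band", "sex"], sort=False):
        q = float(grp["q_yearly"].iloc[0])
        w = _BAND_WEIGHT[AGE_BANDS.index(band)]
        w *= _FEMALE_SHARE if sex == "female" else (1.0 - _FEMALE_SHARE)
        # constant q within the 3-year window (band ageing neglected)
        rows.append({"age_band": band, "sex": sex, "weight": w,
                     "q1": q, "q2": 1 - (1 - q) ** 2, "q3": 1 - (1 - q) ** 3})
    demo = pd.DataFrame(rows)
    demo["weight"] /= demo["weight"].sum()
    return demo


def generate_random_parameter_set(seed: int, ps_template: ParameterSet) -> ParameterSet:
    """A random but valid parameter set for property testing.

    Every non-degenerate probability/cost with an assigned uncertainty
    distribution is scaled by a uniform factor in [0.5, 1.5] (clipped to the
    domain); branch groups are renormalised so the set validates.
    """
    rng = np.random.default_rng(seed)
    ps = ps_template.copy()
    for scope, pv in sorted(ps.iter_entries(), key=lambda e: (str(e[0]), e[1].name)):
        if pv.name in DERIVED_NAMES or pv.psa_distribution not in ("beta", "uniform"):
            continue
        if REGISTRY.get(pv.name, ("",))[0] in ("population", "settings"):
            continue
        if pv.domain in ("probability", "fraction", "utility"):
            if pv.value in (0.0, 1.0):
                continue
            pv.value = float(np.clip(pv.value * rng.uniform(0.5, 1.5), 0.0, 1.0))
        else:
            pv.value = float(pv.value * rng.uniform(0.5, 1.5))
    # keep the utility ordering invariant
    u_i = ps.get("utility_incontinent")
    ps.set_value("utility_success", min(1.0, u_i + rng.uniform(0.0, 1.0 - u_i)))
    renormalise_groups(ps)
    return ps


# ---------------------------------------------------------------------------
# microsimulation oracle

# patient state codes (independent of the cohort engine's labels)
_UNDET, _CONT, _CONTX, _SELF, _SUCC, _IMP = 0, 1, 2, 3, 4, 5
_IMED_GP, _IMED_SP, _IMED_NS, _ITRAIN = 6, 7, 8, 9
_QGP, _QPPT, _QSPEC, _QNS, _QNSMED = 10, 11, 12, 13, 14

_IMPROVED = (_IMP, _IMED_GP, _IMED_SP, _IMED_NS, _ITRAIN)


@dataclass
class MicrosimResult:
    n_patients: int
    seed: int
    occupancy: pd.DataFrame      # cycle x (incontinent, improved, success)

    def se(self, cycle: int, column: str) -> float:
        p = float(self.occupancy.loc[cycle, column])
        return float(np.sqrt(p * (1.0 - p) / self.n_patients))


def _pick(rng, n: int, probs) -> np.ndarray:
    """Categorical draw: returns branch index per patient (len(probs) =
    residual branch is the last index)."""
    edges = np.cumsum(probs)
    r = rng.random(n)
    return np.searchsorted(edges, r)


def microsim_oracle(arm: str, cohort: str, ps: ParameterSet, n_patients: int,
                    seed: int) -> MicrosimResult:
    """Simulate ``n_patients`` individual paths through the care pathway.

    Each decision node is resolved by an independent random draw in a fixed
    node order, so a single seed fully determines every path.  Only the
    parameter values are shared with the cohort engine.
    """
    ps = prepare(ps)
    g = lambda name: ps.get(name, arm)  # noqa: E731
    rng = np.random.default_rng(seed)
    n = int(n_patients)
    horizon = int(ps.get("horizon_cycles"))
    state = np.empty(n, dtype=np.int8)

    # --- entry ------------------------------------------------------------
    if cohort == "incident":
        det = g("detection_incident")
        strat = np.array([g("strategy_cure"), g("strategy_containment"),
                          g("strategy_self")])
        strat = strat / strat.sum()
        detected = rng.random(n) < det
        state[~detected] = _UNDET
        idx = np.flatnonzero(detected)
        branch = _pick(rng, idx.size, strat[:2])
        state[idx[branch == 0]] = _QGP if arm == "current" else _QNS
        state[idx[branch == 1]] = _CONT
        state[idx[branch == 2]] = _SELF
    elif cohort == "prevalent":
        alloc = derive_prevalent_allocation(arm, ps, prepared=True)
        lanes = {"gp": _QGP, "ppt": _QPPT, "specialist": _QSPEC, "ns": _QNS}
        cats, probs = [_UNDET, _CONT, _SELF], [alloc.undetected,
                                               alloc.containment_only,
                                               alloc.self_management]
        for prov, share in alloc.cure_providers.items():
            cats.append(lanes[prov])
            probs.append(alloc.cure * share)
        branch = _pick(rng, n, np.array(probs[:-1]))
        state[:] = np.array(cats, dtype=np.int8)[branch]
    else:
        raise ValueError(f"unknown cohort {cohort!r}")

    def outcome(idx, p_imp, p_succ, improved_to):
        """Resolve one treatment attempt; returns indices of failures."""
        r = rng.random(idx.size)
        state[idx[r < p_succ]] = _SUCC
        imp = (r >= p_succ) & (r < p_succ + p_imp)
        state[idx[imp]] = improved_to
        return idx[r >= p_succ + p_imp]

    occ = []
    for _t in range(1, horizon + 1):
        # continuation states first (mirrors one cycle of care)
        for st, stay, med2, ci, cs in (
                (_IMED_GP, _IMED_GP, "medication_second_cycle",
                 "medication_continue_improvement", "medication_continue_success"),
                (_IMED_SP, _IMED_SP, "medication_second_cycle",
                 "medication_continue_improvement", "medication_continue_success"),
                (_IMED_NS, _IMED_NS, "ns_medication_second_cycle",
                 "ns_medication_continue_improvement", "ns_medication_continue_success")):
            idx = np.flatnonzero(state == st)
            if idx.size:
                cont = rng.random(idx.size) < g(med2)
                state[idx[~cont]] = _IMP
                cidx = idx[cont]
                r = rng.random(cidx.size)
                state[cidx[r < g(cs)]] = _SUCC
                state[cidx[r >= g(cs)]] = stay
        idx = np.flatnonzero(state == _ITRAIN)
        if idx.size:
            cont = rng.random(idx.size) < g("training_continue")
            state[idx[~cont]] = _IMP
            cidx = idx[cont]
            r = rng.random(cidx.size)
            state[cidx[r < g("training_second_success")]] = _SUCC
            state[cidx[r >= g("training_second_success")]] = _IMP

        # queued treatment attempts; immediate referrals chain within the
        # cycle via the pending queue re-scan
        pending = {_QGP: np.flatnonzero(state == _QGP),
                   _QPPT: np.flatnonzero(state == _QPPT),
                   _QSPEC: np.flatnonzero(state == _QSPEC),
                   _QNS: np.flatnonzero(state == _QNS),
                   _QNSMED: np.flatnonzero(state == _QNSMED)}
        nq = {_QGP: [], _QPPT: [], _QSPEC: [], _QNSMED: []}  # next cycle

        def do_ppt(idx):
            if not idx.size:
                return
            b = _pick(rng, idx.size, [g("ppt_rx_pfmt")])
            fails = []
            fails.append(outcome(idx[b == 0], g("ppt_pfmt_improvement"),
                                 g("ppt_pfmt_success"), _ITRAIN))
            fails.append(outcome(idx[b == 1], g("ppt_biofeedback_improvement"),
                                 g("ppt_biofeedback_success"), _ITRAIN))
            fail = np.concatenate(fails)
            r = rng.random(fail.size)
            ref = fail[r < g("ppt_failure_referral")]
            state[fail[r >= g("ppt_failure_referral")]] = _CONTX
            b2 = rng.random(ref.size) < g("ppt_referral_to_gp")
            nq[_QGP].append(ref[b2])
            nq[_QSPEC].append(ref[~b2])

        def do_spec(idx):
            if not idx.size:
                return
            to_ppt = rng.random(idx.size) < g("specialist_to_ppt")
            do_ppt(idx[to_ppt])
            t = idx[~to_ppt]
            if not t.size:
                return
            mix = np.array([g("specialist_rx_surgery"), g("specialist_rx_conservative")])
            b = _pick(rng, t.size, mix)
            fails = [outcome(t[b == 0], g("specialist_surgery_improvement"),
                             g("specialist_surgery_success"), _IMP),
                     outcome(t[b == 1], g("specialist_conservative_improvement"),
                             g("specialist_conservative_success"), _IMP),
                     outcome(t[b == 2], g("specialist_medication_improvement"),
                             g("specialist_medication_success"), _IMED_SP)]
            fail = np.concatenate(fails)
            r = rng.random(fail.size)
            ref = fail[r < g("specialist_failure_referral")]
            state[fail[r >= g("specialist_failure_referral")]] = _CONTX
            b2 = rng.random(ref.size) < g("specialist_referral_to_gp")
            nq[_QGP].append(ref[b2])
            nq[_QPPT].append(ref[~b2])

        def do_gp(idx):
            if not idx.size:
                return
            ref_now = rng.random(idx.size) < g("gp_immediate_referral")
            ridx = idx[ref_now]
            b = rng.random(ridx.size) < g("gp_referral_to_ppt")
            do_ppt(ridx[b])
            do_spec(ridx[~b])
            att = idx[~ref_now]
            if not att.size:
                return
            mix = np.array([g("gp_rx_medication"), g("gp_rx_lifestyle"), g("gp_rx_uti")])
            b = _pick(rng, att.size, mix)
            fails = [outcome(att[b == 0], g("gp_medication_improvement"),
                             g("gp_medication_success"), _IMED_GP),
                     outcome(att[b == 1], g("gp_lifestyle_improvement"),
                             g("gp_lifestyle_success"), _IMP),
                     outcome(att[b == 2], g("gp_uti_improvement"),
                             g("gp_uti_success"), _IMP),
                     outcome(att[b == 3], g("gp_training_improvement"),
                             g("gp_training_success"), _IMP)]
            fail = np.concatenate(fails)
            r = rng.random(fail.size)
            ref = fail[r < g("gp_immediate_referral")]
            state[fail[r >= g("gp_immediate_referral")]] = _CONTX
            b2 = rng.random(ref.size) < g("gp_referral_to_ppt")
            nq[_QPPT].append(ref[b2])
            nq[_QSPEC].append(ref[~b2])

        def do_ns(idx):
            if not idx.size:
                return
            b = _pick(rng, idx.size, [g("ns_initial_share")])
            fails = [outcome(idx[b == 0], g("ns_initial_improvement"),
                             g("ns_initial_success"), _IMP),
                     outcome(idx[b == 1], g("ns_uti_improvement"),
                             g("ns_uti_success"), _IMP)]
            fail = np.concatenate(fails)
            cont = rng.random(fail.size) < g("ns_failure_continue")
            cidx = fail[cont]
            med = rng.random(cidx.size) < g("ns_rx_medication")
            nq[_QNSMED].append(cidx[med])
            state[cidx[~med]] = _CONTX
            ref = fail[~cont]
            b2 = rng.random(ref.size) < g("ns_referral_to_ppt")
            nq[_QPPT].append(ref[b2])
            nq[_QSPEC].append(ref[~b2])

        def do_ns_med(idx):
            if not idx.size:
                return
            fail = outcome(idx, g("ns_medication_improvement"),
                           g("ns_medication_success"), _IMED_NS)
            r = rng.random(fail.size)
            ref = fail[r < g("ns_failure_referral")]
            state[fail[r >= g("ns_failure_referral")]] = _CONTX
            b2 = rng.random(ref.size) < g("ns_referral_to_ppt")
            nq[_QPPT].append(ref[b2])
            nq[_QSPEC].append(ref[~b2])

        do_gp(pending[_QGP])
        do_ppt(pending[_QPPT])
        do_spec(pending[_QSPEC])
        do_ns(pending[_QNS])
        do_ns_med(pending[_QNSMED])
        for qs, chunks in nq.items():
            for c in chunks:
                state[c] = qs

        succ = float(np.mean(state == _SUCC))
        imp = float(np.mean(np.isin(state, _IMPROVED)))
        occ.append({"incontinent": 1.0 - succ - imp, "improved": imp,
                    "success": succ})

    df = pd.DataFrame(occ, index=pd.RangeIndex(1, horizon + 1, name="cycle"))
    return MicrosimResult(n_patients=n, seed=seed, occupancy=df)
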