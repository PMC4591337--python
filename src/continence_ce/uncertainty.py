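"""One-way and probabilistic sensitivity analysis.

OWSA perturbs each non-structural input by ±40% of its mean (probabilities
capped at 1, branch groups renormalised) and recomputes the per-patient
incrementals.  The PSA jointly samples all non-structural inputs: beta
distributions (method-of-moments, SD = ``se_frac`` × mean) for parameters
bounded in [0, 1], uniform on mean × (1 ± ``se_frac``) for costs and other
unbounded inputs.

Two inputs are sampled in correlated form rather than independently:
the new-care incident detection rate is current detection plus the sampled
NS-attributable gain, and the success-state utility is the sampled
incontinent-state utility plus the fixed base-case decrement.  Sampling the
absolute pairs independently would make new care detect fewer patients than
current care, or invert the utility ordering, in a large share of draws —
structural sign flips rather than parameter uncertainty.  The QALY
difference between arms depends on the utility decrement, not the levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import per_patient_results
from .params import (DERIVED_NAMES, REGISTRY, RESIDUAL_NAMES, ParameterSet,
                     apply_residual_complements, renormalise_groups)

#: blocks whose entries are structural and never varied
_STRUCTURAL_BLOCKS = ("population", "settings")
#: entries handled via a correlated rule instead of direct sampling
_LINKED = ("utility_success",)


def eligible_parameters(ps: ParameterSet,
                        include_residuals: bool = True) -> list[tuple[str | None, str, str]]:
    """(scope, name, distribution) of every parameter varied in OWSA/PSA.

    Residual branches (complements computed as 1 − sum of their group) are
    varied one-way but not sampled jointly (``include_residuals=False``)."""
    out = []
    for scope, pv in ps.iter_entries():
        if pv.name in DERIVED_NAMES or pv.name in _LINKED:
            continue
        if pv.psa_distribution not in ("beta", "uniform"):
            continue
        if REGISTRY.get(pv.name, ("",))[0] in _STRUCTURAL_BLOCKS:
            continue
        if not include_residuals and (scope, pv.name) in RESIDUAL_NAMES:
            continue
        out.append((scope, pv.name, pv.psa_distribution))
    return sorted(out, key=lambda e: (str(e[0]), e[1]))


def _set_linked_utility(ps: ParameterSet, base: ParameterSet) -> None:
    decrement = base.get("utility_success") - base.get("utility_incontinent")
    ps.set_value("utility_success",
                 min(1.0, ps.get("utility_incontinent") + decrement))


# ---------------------------------------------------------------------------
# one-way sensitivity


def one_way_sensitivity(ps: ParameterSet, range_frac: float = 0.4,
                        skipped: list | None = None) -> pd.DataFrame:
    """Tornado table: low/high incrementals at mean ± ``range_frac``.

    Returns a frame with one row per parameter, columns for the societal
    cost and QALY incrementals at both ends, sorted by the societal range.
    Parameters whose perturbation cannot produce a runnable set are skipped
    and reported through ``skipped``.
    """
    base = per_patient_results(ps)
    rows = []
    for scope, name, _dist in eligible_parameters(ps):
        res = {}
        try:
            for tag, factor in (("low", 1.0 - range_frac), ("high", 1.0 + range_frac)):
                trial = ps.copy()
                value = trial.get(name, scope) * factor
                if trial.entry(name, scope).domain in ("probability", "fraction",
                                                       "utility"):
                    value = min(value, 1.0)
                trial.set_value(name, value, arm=scope)
                _set_linked_utility(trial, ps)
                renormalise_groups(trial)
                rt = per_patient_results(trial)
                res[tag] = (rt.delta_societal, rt.delta_payer, rt.delta_qalys)
        except Exception as err:  # invalidated beyond repair: skip and log
            if skipped is not None:
                skipped.append((scope, name, repr(err)))
            continue
        rows.append({
            "parameter": name, "arm": scope or "shared",
            "base_value": ps.get(name, scope),
            "dcost_societal_low": res["low"][0], "dcost_societal_high": res["high"][0],
            "dcost_payer_low": res["low"][1], "dcost_payer_high": res["high"][1],
            "dqaly_low": res["low"][2], "dqaly_high": res["high"][2],
        })
    df = pd.DataFrame(rows)
    df["range"] = (df["dcost_societal_high"] - df["dcost_societal_low"]).abs()
    df["base_dcost_societal"] = base.delta_societal
    return df.sort_values("range", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# probabilistic sensitivity


def beta_shapes(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments beta shapes for a mean in (0, 1); infeasible
    variances (sd² ≥ mean(1−mean)) are clamped to 95% of the feasible
    maximum."""
    if not (0.0 < mean < 1.0):
        raise ValueError("beta mean must lie strictly in (0, 1)")
    sd_max = np.sqrt(mean * (1.0 - mean))
    sd = min(sd, 0.95 * sd_max)
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    return mean * nu, (1.0 - mean) * nu


def sample_parameter_set(ps: ParameterSet, se_frac: float,
                         rng: np.random.Generator) -> ParameterSet:
    """One joint draw of all non-structural parameters."""
    out = ps.copy()
    for scope, name, dist in eligible_parameters(ps, include_residuals=False):
        mean = ps.get(name, scope)
        if dist == "beta":
            if mean <= 0.0 or mean >= 1.0:
                continue  # degenerate: stays fixed
            a, b = beta_shapes(mean, se_frac * mean)
            value = float(rng.beta(a, b))
        else:
            value = float(rng.uniform(mean * (1.0 - se_frac),
                                      mean * (1.0 + se_frac)))
        out.set_value(name, value, arm=scope)
    _set_linked_utility(out, ps)
    apply_residual_complements(out)
    return out


@dataclass
class PSASummary:
    n_draws: int
    se_frac: float
    seed: int
    draws: pd.DataFrame = field(repr=False)  # one row per draw

    @property
    def p_cost_saving(self) -> float:
        """Probability of societal cost savings."""
        return float((self.draws["dcost_societal"] < 0).mean())

    @property
    def p_cost_saving_payer(self) -> float:
        return float((self.draws["dcost_payer"] < 0).mean())

    @property
    def p_fewer_qalys(self) -> float:
        return float((self.draws["dqaly"] < 0).mean())

    @property
    def p_dominant(self) -> float:
        """Probability that new care is cost-saving and more effective."""
        return float(((self.draws["dcost_societal"] < 0)
                      & (self.draws["dqaly"] > 0)).mean())

    def percentiles(self, column: str, q=(2.5, 97.5)) -> tuple[float, float]:
        lo, hi = np.percentile(self.draws[column], q)
        return float(lo), float(hi)

    def to_json_dict(self) -> dict:
        ci_c = self.percentiles("dcost_societal")
        ci_q = self.percentiles("dqaly")
        return {
            "n_draws": self.n_draws, "se_frac": self.se_frac, "seed": self.seed,
            "p_cost_saving": self.p_cost_saving,
            "p_cost_saving_payer": self.p_cost_saving_payer,
            "p_fewer_qalys": self.p_fewer_qalys,
            "p_dominant": self.p_dominant,
            "dcost_societal_ci95": ci_c, "dqaly_ci95": ci_q,
        }


def probabilistic_sensitivity(ps: ParameterSet, n_draws: int = 1000,
                              se_frac: float = 0.2, seed: int = 0) -> PSASummary:
    """Joint PSA: ``n_draws`` sampled parameter sets, each run through the
    full per-patient pipeline; reproducible given the seed."""
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    rng = np.random.default_rng(seed)
    recs = []
    for _ in range(n_draws):
        drawn = sample_parameter_set(ps, se_frac, rng)
        rt = per_patient_results(drawn)
        recs.append({"dcost_societal": rt.delta_societal,
                     "dcost_payer": rt.delta_payer,
                     "dqaly": rt.delta_qalys})
    return PSASummary(n_draws=n_draws, se_frac=se_frac, seed=seed,
                      draws=pd.DataFrame(recs))


# ---------------------------------------------------------------------------
# plotting (lazy matplotlib imports)


def plot_tornado(table: pd.DataFrame, top: int = 15, ax=None):
    """Horizontal tornado of the societal cost incrementals."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(7, 0.4 * min(top, len(table)) + 1))
    sub = table.head(top).iloc[::-1]
    base = float(sub["base_dcost_societal"].iloc[0])
    lo = np.minimum(sub["dcost_societal_low"], sub["dcost_societal_high"])
    hi = np.maximum(sub["dcost_societal_low"], sub["dcost_societal_high"])
    ax.barh(sub["parameter"], hi - lo, left=lo, color="#4878a8")
    ax.axvline(base, color="k", lw=1)
    ax.set_xlabel("incremental societal cost (EUR/patient/3yr)")
    return ax


def plot_psa_scatter(summary: PSASummary, ax=None):
    """Cost-effectiveness plane of the PSA draws (societal perspective)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(summary.draws["dqaly"], summary.draws["dcost_societal"],
               s=6, alpha=0.35, edgecolors="none")
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("incremental QALYs per patient")
    ax.set_ylabel("incremental societal cost (EUR)")
    return ax
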