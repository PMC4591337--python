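"""National 3-year budget impact with yearly incident inflow and attrition.

Year 1 covers all prevalent and incident patients; years 2 and 3 each add a
fresh incident cohort.  Patients already in the pathway leave it through
death (stratum-weighted, from a demography table) or nursing-home admission
(4% per year in the base case); attrition applies at year boundaries,
uniformly across pathway states, and exited patients accrue no further
costs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import economics as ec
from . import pathway as pw
from .params import ParameterSet, prepare, target_population

DEMOGRAPHY_COLUMNS = ("age_band", "sex", "weight", "q1", "q2", "q3")


@dataclass
class Demography:
    """Age–sex strata with weights and cumulative 1/2/3-year death
    probabilities."""

    table: pd.DataFrame

    def __post_init__(self):
        missing = set(DEMOGRAPHY_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"demography table missing columns {sorted(missing)}")
        q = self.table[["q1", "q2", "q3"]].to_numpy()
        if (q < 0).any() or (q > 1).any():
            raise ValueError("death probabilities must lie in [0, 1]")
        if (q[:, 1] < q[:, 0]).any() or (q[:, 2] < q[:, 1]).any():
            raise ValueError("cumulative death probabilities must be non-decreasing")
        w = self.table["weight"].to_numpy()
        if abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("stratum weights must sum to 1")

    @classmethod
    def from_csv(cls, path) -> "Demography":
        return cls(pd.read_csv(path))

    def survival(self, years: int) -> float:
        """Stratum-weighted probability of being alive after ``years``."""
        if years <= 0:
            return 1.0
        q = self.table[f"q{min(years, 3)}"].to_numpy()
        return float((self.table["weight"].to_numpy() * (1.0 - q)).sum())


ZERO_ATTRITION = Demography(pd.DataFrame(
    [{"age_band": "all", "sex": "all", "weight": 1.0, "q1": 0.0, "q2": 0.0, "q3": 0.0}]))


@dataclass
class BudgetImpactTable:
    totals: dict  # {arm: {"societal": eur, "payer": eur}}

    @property
    def incremental(self) -> dict:
        return {p: self.totals["new"][p] - self.totals["current"][p]
                for p in ("societal", "payer")}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"New care": self.totals["new"],
                           "Usual care": self.totals["current"]})
        df["Incremental"] = df["New care"] - df["Usual care"]
        df.index = ["Societal perspective", "Health care payer perspective"]
        return df


def project_budget_impact(ps: ParameterSet, demo: Demography,
                          years: int = 3, inflow: bool = True) -> BudgetImpactTable:
    """National cost totals over ``years`` for both arms.

    Each cohort's per-patient per-cycle cost stream (from the per-patient
    engine) is scaled by its national headcount and attenuated at its year
    boundaries by stratum-weighted survival times the nursing-home retention
    factor; cycles beyond the calendar window are dropped.
    """
    ps = prepare(ps)
    nh = ps.get("nursing_home_exit_yearly")
    if not (0.0 <= nh <= 1.0):
        raise ValueError("nursing-home exit rate must lie in [0, 1]")
    pop = target_population(ps)
    cycles_per_year = round(1.0 / ps.get("cycle_length_years"))

    # (cohort, headcount, entry year)
    cohorts = [("prevalent", pop["prevalent"], 1), ("incident", pop["incident_yearly"], 1)]
    if inflow:
        cohorts += [("incident", pop["incident_yearly"], y) for y in range(2, years + 1)]

    totals = {}
    for arm in ("current", "new"):
        streams = {}
        for cohort in ("prevalent", "incident"):
            trace = pw.run_cohort(arm, cohort, ps, prepared=True)
            streams[cohort] = ec.trace_costs(trace, ps)
        soc = payer = 0.0
        for cohort, n, entry in cohorts:
            max_cycles = min(len(streams[cohort]), (years - entry + 1) * cycles_per_year)
            for t in range(1, max_cycles + 1):
                age = (t - 1) // cycles_per_year  # completed cohort years
                alive = demo.survival(age) * (1.0 - nh) ** age
                cv = streams[cohort][t - 1]
                soc += n * alive * cv.societal_total
                payer += n * alive * cv.payer_total
        totals[arm] = {"societal": soc, "payer": payer}
    return BudgetImpactTable(totals=totals)
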