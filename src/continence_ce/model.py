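"""Model/Results facade over the decision-analytic pipeline.

:class:`ContinenceCareModel` wraps a parameter set; :meth:`run` executes the
two-strategy comparison on the mixed national cohort and returns a
:class:`CEResults` carrying the cost table, QALYs, outcome shares and the
incremental analysis, with ``summary()`` producing a readable report.
Sensitivity analyses, scenarios and the budget impact hang off the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import budget as bu
from . import economics as ec
from . import pathway as pw
from . import scenarios as sc
from . import synthetic as sy
from . import uncertainty as un
from .params import (ParameterSet, base_case_parameters, prepare,
                     target_population, validate_parameter_set)


@dataclass
class CEResults:
    """Results of one two-strategy comparison."""

    params: ParameterSet = field(repr=False)
    results: ec.ResultsTable
    scenario: str | None = None

    # -- convenience accessors ----------------------------------------------
    @property
    def delta_societal(self) -> float:
        return self.results.delta_societal

    @property
    def delta_payer(self) -> float:
        return self.results.delta_payer

    @property
    def delta_qalys(self) -> float:
        return self.results.delta_qalys

    def icer(self, perspective: str = "societal") -> sc.IcerResult:
        dc = {"societal": self.delta_societal, "payer": self.delta_payer}[perspective]
        return sc.icer(dc, self.delta_qalys)

    def outcomes_frame(self) -> pd.DataFrame:
        rows = {}
        for cohort in ("incident", "prevalent"):
            for arm, label in (("current", "Usual care"), ("new", "New care")):
                o = self.results.__getattribute__(arm).outcomes[cohort]
                rows[(cohort, label)] = {"% success": o.pct_success,
                                         "% improved": o.pct_improved,
                                         "% not improved": o.pct_not_improved}
        return pd.DataFrame(rows).T

    def summary(self) -> str:
        head = "Continence-care cost-effectiveness"
        if self.scenario:
            head += f" — scenario: {self.scenario}"
        table = self.results.to_frame().round(2)
        outcomes = self.outcomes_frame().round(1)
        ic = self.icer("societal")
        verdict = ic.classification
        if ic.icer is not None:
            verdict += f" ({ic.icer:,.0f} EUR/QALY)"
        lines = [
            head, "=" * len(head), "",
            "Per-patient costs and QALYs over 3 years (EUR):",
            table.to_string(), "",
            "Outcome shares at 3 years (% of cohort):",
            outcomes.to_string(), "",
            f"Incremental societal cost : {self.delta_societal:10.2f} EUR",
            f"Incremental payer cost    : {self.delta_payer:10.2f} EUR",
            f"Incremental QALYs         : {self.delta_qalys:10.5f}",
            f"New care vs usual care    : {verdict}",
        ]
        return "\n".join(lines)


class ContinenceCareModel:
    """Two-strategy decision model for urinary-incontinence care.

    Parameters default to the published base case.  ``run()`` performs the
    deterministic comparison; ``one_way`` / ``psa`` quantify parameter
    uncertainty; ``run_scenario`` evaluates the predefined policy
    scenarios; ``budget_impact`` projects national 3-year totals.
    """

    def __init__(self, params: ParameterSet | None = None):
        self.params = prepare(params) if params is not None else base_case_parameters()
        report = validate_parameter_set(self.params)
        if not report.ok:
            raise ValueError(f"invalid parameter set:\n{report}")

    @classmethod
    def from_config(cls, path) -> "ContinenceCareModel":
        return cls(ParameterSet.from_yaml(path))

    # -- core ---------------------------------------------------------------
    def run(self) -> CEResults:
        return CEResults(params=self.params,
                         results=ec.per_patient_results(self.params, prepared=True))

    def run_cohort(self, arm: str, cohort: str) -> pw.CohortTrace:
        return pw.run_cohort(arm, cohort, self.params, prepared=True)

    def target_population(self) -> dict[str, int]:
        return target_population(self.params)

    # -- scenarios and uncertainty ------------------------------------------
    def run_scenario(self, name: str) -> CEResults:
        return CEResults(params=self.params, scenario=name,
                         results=sc.run_scenario(name, self.params))

    def one_way(self, range_frac: float = 0.4) -> pd.DataFrame:
        return un.one_way_sensitivity(self.params, range_frac=range_frac)

    def psa(self, n_draws: int = 1000, se_frac: float = 0.2,
            seed: int = 0) -> un.PSASummary:
        return un.probabilistic_sensitivity(self.params, n_draws=n_draws,
                                            se_frac=se_frac, seed=seed)

    def budget_impact(self, demography: bu.Demography | None = None,
                      seed: int = 0, years: int = 3) -> bu.BudgetImpactTable:
        if demography is None:
            demography = bu.Demography(sy.generate_demography(seed))
        return bu.project_budget_impact(self.params, demography, years=years)
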