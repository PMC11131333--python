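"""End-to-end scale-up pipeline: demand → workforce → costs.

A :class:`ScaleUpScenario` bundles the three parameter blocks
(population, capacity, unit costs); :func:`run_scaleup` evaluates the
whole chain at fixed parameter values and returns every scalar output
in one flat mapping.  The Monte Carlo layer re-evaluates this function
under sampled parameters, so it must stay a pure, cheap function of the
scenario.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .costing import (
    UnitCosts,
    diagnostics_cost,
    medication_cost,
    personnel_cost,
    soc_premium_fraction,
    total_costs,
)
from .demand_projection import (
    PopulationInputs,
    coverage_metrics,
    estimate_patient_counts,
    project_annual_visits,
)
from .tms_core import Arm
from .workforce_capacity import CapacityParams, annual_capacity, nurses_required

__all__ = ["ScaleUpScenario", "run_scaleup"]


@dataclass
class ScaleUpScenario:
    """All inputs of the national scale-up computation."""

    population: PopulationInputs = field(default_factory=PopulationInputs)
    capacity: CapacityParams = field(default_factory=CapacityParams)
    costs: UnitCosts = field(default_factory=UnitCosts)

    def copy(self) -> "ScaleUpScenario":
        return ScaleUpScenario(
            population=dataclasses.replace(self.population),
            capacity=dataclasses.replace(
                self.capacity,
                visits_per_nurse_year=dict(self.capacity.visits_per_nurse_year),
                workday_min=dict(self.capacity.workday_min),
                care_fraction=dict(self.capacity.care_fraction),
                visit_minutes=dict(self.capacity.visit_minutes),
            ),
            costs=dataclasses.replace(
                self.costs,
                diagnostics_usd_year=dict(self.costs.diagnostics_usd_year),
            ),
        )


def run_scaleup(scenario: ScaleUpScenario) -> dict[str, float]:
    """Evaluate demand, workforce and costs; return all scalar outputs.

    Keys: ``total_patients``, ``annual_visits``, ``fold_increase``,
    ``realized_visit_share``, ``care_seeking_share``, and per-arm
    (prefixes ``soc_`` / ``int_``): ``capacity``, ``nurses``,
    ``personnel_salary``, ``personnel_training``, ``personnel_total``,
    ``medication_total``, ``diagnostics_total``, ``total_cost``,
    ``cost_per_visit``; plus ``soc_premium_fraction``.
    """
    pop = scenario.population
    pop.validate()
    total = estimate_patient_counts(
        pop.dm_patients.value, pop.htn_patients.value, pop.comorbid_patients.value)
    visits = project_annual_visits(total, pop.visits_per_patient_year)
    cov = coverage_metrics(pop, visits, total)

    out: dict[str, float] = {
        "total_patients": float(total),
        "annual_visits": float(visits),
        "fold_increase": cov.fold_increase,
        "realized_visit_share": cov.realized_visit_share,
        "care_seeking_share": cov.care_seeking_share,
    }

    med = medication_cost(pop.dm_patients.value, pop.htn_patients.value, scenario.costs)
    for arm, prefix in ((Arm.SOC, "soc"), (Arm.INTERVENTION, "int")):
        cap = annual_capacity(scenario.capacity, arm)
        wf = nurses_required(visits, cap, arm=arm)
        pers = personnel_cost(wf.nurses_required, scenario.costs)
        diag = diagnostics_cost(scenario.costs, arm, dm_related_visits=visits)
        breakdown = total_costs(arm, pers, med, diag, visits)
        out[f"{prefix}_capacity"] = cap
        out[f"{prefix}_nurses"] = float(wf.nurses_required)
        out[f"{prefix}_personnel_salary"] = breakdown.personnel_salary
        out[f"{prefix}_personnel_training"] = breakdown.personnel_training
        out[f"{prefix}_personnel_total"] = breakdown.personnel_total
        out[f"{prefix}_medication_dm"] = breakdown.medication_dm
        out[f"{prefix}_medication_htn"] = breakdown.medication_htn
        out[f"{prefix}_medication_total"] = breakdown.medication_total
        out[f"{prefix}_diagnostics_total"] = breakdown.diagnostics_total
        out[f"{prefix}_total_cost"] = breakdown.grand_total
        out[f"{prefix}_cost_per_visit"] = (
            breakdown.cost_per_visit if breakdown.cost_per_visit is not None
            else float("nan")
        )
    out["soc_premium_fraction"] = (
        out["soc_total_cost"] / out["int_total_cost"] - 1.0
        if out["int_total_cost"] > 0 else float("nan")
    )
    return out
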