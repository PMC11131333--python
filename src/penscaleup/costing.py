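"""Bottom-up cost aggregation for national DM/HTN care scale-up.

Components, per study arm:

* personnel — required nurses × annual salary, plus a one-off economic
  opportunity cost of training per nurse;
* medication — per-patient annual drug costs ($7.71 diabetes, $3.15
  hypertension) times the national patient counts; comorbid patients
  incur both conditions' drug costs, so the two condition totals use
  the raw DM and HTN counts;
* diagnostics — either a directly configured per-arm annual total, or a
  component build-up (annualised sphygmomanometer and glucometer device
  cost per facility plus glucose test strips per DM-related visit).

All internal arithmetic is in USD at full precision; local-currency
amounts convert at the configured SZL-per-USD rate (default 18.867,
the June 2023 rate).  Rounding happens only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .tms_core import Arm

__all__ = [
    "DiagnosticsComponents",
    "UnitCosts",
    "PersonnelCost",
    "MedicationCost",
    "CostBreakdown",
    "szl_to_usd",
    "usd_to_szl",
    "personnel_cost",
    "medication_cost",
    "diagnostics_cost",
    "total_costs",
    "soc_premium_fraction",
    "CostConfigError",
]

#: June 2023 exchange rate: 1 USD = 18.867 SZL.
DEFAULT_SZL_PER_USD = 18.867


class CostConfigError(ValueError):
    """Unit-cost configuration is incomplete or invalid."""


@dataclass
class DiagnosticsComponents:
    """Component prices for the diagnostics build-up (USD)."""

    sphygmomanometer_usd: float
    glucometer_usd: float
    device_lifespan_years: float
    strip_usd: float
    strips_per_dm_visit: float
    n_facilities: int

    def annual_total(self, dm_related_visits: float) -> float:
        if self.device_lifespan_years <= 0:
            raise CostConfigError("device lifespan must be positive")
        devices = (
            (self.sphygmomanometer_usd + self.glucometer_usd)
            / self.device_lifespan_years
            * self.n_facilities
        )
        strips = self.strip_usd * self.strips_per_dm_visit * dm_related_visits
        return devices + strips


@dataclass
class UnitCosts:
    """Unit costs in USD.  Salary and training defaults are back-calculated
    from the published per-arm personnel totals divided by the published
    headcounts, and can be overridden from configuration."""

    nurse_salary_usd_year: float = 8_077.0
    training_usd_per_nurse: float = 129.0
    med_dm_usd_patient_year: float = 7.71
    med_htn_usd_patient_year: float = 3.15
    diagnostics_usd_year: dict[Arm, float] = field(default_factory=lambda: {
        Arm.SOC: 174_900.0, Arm.INTERVENTION: 173_310.0,
    })
    diagnostics_components: Optional[DiagnosticsComponents] = None
    szl_per_usd: float = DEFAULT_SZL_PER_USD

    def validate(self) -> None:
        if self.szl_per_usd <= 0:
            raise CostConfigError("exchange rate must be positive")
        rates = [
            self.nurse_salary_usd_year, self.training_usd_per_nurse,
            self.med_dm_usd_patient_year, self.med_htn_usd_patient_year,
        ]
        if any(r < 0 for r in rates):
            raise CostConfigError("unit costs must be non-negative")


@dataclass
class PersonnelCost:
    salary: float
    training: float

    @property
    def total(self) -> float:
        return self.salary + self.training


@dataclass
class MedicationCost:
    dm: float
    htn: float

    @property
    def total(self) -> float:
        return self.dm + self.htn


@dataclass
class CostBreakdown:
    """Per-arm cost totals (USD) with the per-visit unit cost."""

    arm: Arm
    personnel_salary: float
    personnel_training: float
    personnel_total: float
    medication_dm: float
    medication_htn: float
    medication_total: float
    diagnostics_total: float
    grand_total: float
    cost_per_visit: Optional[float]   # None when annual visits are zero


def szl_to_usd(amount_szl: float, szl_per_usd: float = DEFAULT_SZL_PER_USD) -> float:
    if amount_szl < 0:
        raise ValueError("amount must be non-negative")
    if szl_per_usd <= 0:
        raise CostConfigError("exchange rate must be positive")
    return amount_szl / szl_per_usd


def usd_to_szl(amount_usd: float, szl_per_usd: float = DEFAULT_SZL_PER_USD) -> float:
    if amount_usd < 0:
        raise ValueError("amount must be non-negative")
    if szl_per_usd <= 0:
        raise CostConfigError("exchange rate must be positive")
    return amount_usd * szl_per_usd


def personnel_cost(nurses: int, unit_costs: UnitCosts) -> PersonnelCost:
    """Salary plus training opportunity cost for the required nurses."""
    if nurses < 0:
        raise ValueError("nurse count must be non-negative")
    unit_costs.validate()
    return PersonnelCost(
        salary=nurses * unit_costs.nurse_salary_usd_year,
        training=nurses * unit_costs.training_usd_per_nurse,
    )


def medication_cost(
    dm_patients: float, htn_patients: float, unit_costs: UnitCosts
) -> MedicationCost:
    """Annual drug costs; comorbid patients are counted in both condition
    totals (the condition counts already include them)."""
    if dm_patients < 0 or htn_patients < 0:
        raise ValueError("patient counts must be non-negative")
    unit_costs.validate()
    return MedicationCost(
        dm=dm_patients * unit_costs.med_dm_usd_patient_year,
        htn=htn_patients * unit_costs.med_htn_usd_patient_year,
    )


def diagnostics_cost(
    unit_costs: UnitCosts,
    arm: Arm,
    dm_related_visits: Optional[float] = None,
) -> float:
    """Annual diagnostics total for one arm.

    Uses the component build-up when component prices are configured;
    otherwise the direct per-arm total.  Raises
    :class:`CostConfigError` when neither is available.
    """
    unit_costs.validate()
    if unit_costs.diagnostics_components is not None:
        if dm_related_visits is None:
            raise CostConfigError(
                "component diagnostics mode needs the DM-related visit count"
            )
        return unit_costs.diagnostics_components.annual_total(dm_related_visits)
    if arm not in unit_costs.diagnostics_usd_year:
        raise CostConfigError(f"no diagnostics total configured for arm {arm}")
    return float(unit_costs.diagnostics_usd_year[arm])


def total_costs(
    arm: Arm,
    personnel: PersonnelCost,
    medication: MedicationCost,
    diagnostics_total: float,
    annual_visits: int,
) -> CostBreakdown:
    """Assemble the per-arm breakdown; the grand total is exactly the sum
    of its three components, and the per-visit cost is flagged (None)
    when there are no visits."""
    grand = personnel.total + medication.total + diagnostics_total
    per_visit = grand / annual_visits if annual_visits > 0 else None
    return CostBreakdown(
        arm=arm,
        personnel_salary=personnel.salary,
        personnel_training=personnel.training,
        personnel_total=personnel.total,
        medication_dm=medication.dm,
        medication_htn=medication.htn,
        medication_total=medication.total,
        diagnostics_total=diagnostics_total,
        grand_total=grand,
        cost_per_visit=per_visit,
    )


def soc_premium_fraction(soc: CostBreakdown, intervention: CostBreakdown) -> float:
    """How much more the standard-of-care scale-up costs, as a fraction of
    the intervention total (0.66 means 66% more expensive)."""
    if intervention.grand_total <= 0:
        raise ValueError("intervention total must be positive")
    return soc.grand_total / intervention.grand_total - 1.0
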