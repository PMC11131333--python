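"""Nurse requirements for projected DM/HTN visit volumes.

Two capacity modes are supported:

* ``MECHANISTIC`` — a transparent throughput formula built from the
  observed time-and-motion quantities: a nurse's annual DM/HTN visit
  capacity is ``workday minutes × patient-care fraction × DM/HTN focus
  fraction × working days per year ÷ weighted minutes per visit``, with
  the weighted minutes mixing new-visit and follow-up DM/HTN visit
  durations at the observed new-visit share.
* ``CALIBRATED`` — a directly supplied annual visits-per-nurse figure.
  The defaults (821 standard-of-care, 1,443 intervention visits per
  nurse-year) are back-calculated from the published national headcount
  requirements and are far below the mechanistic full-time throughput,
  reflecting that observed nurses handle the full patient mix and many
  duties besides DM/HTN care.

Headcounts use ceiling division ("at least" semantics — the workforce
is never sized below demand).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .tms_core import Arm, VisitType

__all__ = [
    "CapacityMode",
    "CapacityParams",
    "WorkforceResult",
    "annual_capacity",
    "nurses_required",
    "CapacityError",
]


class CapacityError(ValueError):
    """Capacity parameters do not define a positive throughput."""


class CapacityMode(str, Enum):
    MECHANISTIC = "MECHANISTIC"
    CALIBRATED = "CALIBRATED"


def _default_visit_minutes() -> dict[tuple[Arm, VisitType], float]:
    # DM/HTN visit durations from the time-per-patient table (minutes)
    return {
        (Arm.SOC, VisitType.NEW): 16.7,
        (Arm.SOC, VisitType.FOLLOW_UP): 10.2,
        (Arm.INTERVENTION, VisitType.NEW): 11.0,
        (Arm.INTERVENTION, VisitType.FOLLOW_UP): 8.7,
    }


@dataclass
class CapacityParams:
    """Inputs of the nurse-capacity computation.

    ``visits_per_nurse_year`` drives CALIBRATED mode; the mechanistic
    fields drive MECHANISTIC mode.  ``working_days_per_year`` defaults
    to 230 (260 weekdays less leave and public holidays).
    """

    mode: CapacityMode = CapacityMode.CALIBRATED
    workday_min: dict[Arm, float] = field(default_factory=lambda: {
        Arm.SOC: 497.0, Arm.INTERVENTION: 516.0,
    })
    care_fraction: dict[Arm, float] = field(default_factory=lambda: {
        Arm.SOC: 0.6861, Arm.INTERVENTION: 0.7282,
    })
    visit_minutes: dict[tuple[Arm, VisitType], float] = field(
        default_factory=_default_visit_minutes)
    new_visit_share: float = 0.06
    working_days_per_year: int = 230
    dm_htn_focus_fraction: float = 1.0
    visits_per_nurse_year: dict[Arm, float] = field(default_factory=lambda: {
        # back-calculated so that the projected national demand yields
        # the published headcounts under ceiling division
        Arm.SOC: 821.0, Arm.INTERVENTION: 1443.0,
    })

    def validate(self) -> None:
        if not (0.0 <= self.new_visit_share <= 1.0):
            raise CapacityError("new_visit_share must lie in [0, 1]")
        for arm in Arm:
            if self.workday_min[arm] <= 0:
                raise CapacityError("workday minutes must be positive")
            if not (0.0 < self.care_fraction[arm] <= 1.0):
                raise CapacityError("care fraction must lie in (0, 1]")
        if self.working_days_per_year <= 0:
            raise CapacityError("working days per year must be positive")
        if not (0.0 <= self.dm_htn_focus_fraction <= 1.0):
            raise CapacityError("focus fraction must lie in [0, 1]")


@dataclass
class WorkforceResult:
    arm: Arm
    annual_capacity_visits_per_nurse: float
    nurses_required: int
    demand_minutes_per_year: float


def annual_capacity(params: CapacityParams, arm: Arm) -> float:
    """Annual DM/HTN visits one nurse can serve, per the configured mode."""
    params.validate()
    if params.mode is CapacityMode.CALIBRATED:
        cap = params.visits_per_nurse_year[arm]
        if cap <= 0:
            raise CapacityError("calibrated visits_per_nurse_year must be positive")
        return float(cap)
    weighted_min = (
        params.new_visit_share * params.visit_minutes[(arm, VisitType.NEW)]
        + (1.0 - params.new_visit_share) * params.visit_minutes[(arm, VisitType.FOLLOW_UP)]
    )
    if weighted_min <= 0:
        raise CapacityError("weighted visit minutes must be positive")
    cap = (
        params.workday_min[arm]
        * params.care_fraction[arm]
        * params.dm_htn_focus_fraction
        * params.working_days_per_year
        / weighted_min
    )
    if cap <= 0:
        raise CapacityError("focus fraction of zero yields no capacity")
    return cap


def nurses_required(
    annual_visits: int,
    capacity: float,
    arm: Optional[Arm] = None,
    mean_visit_minutes: Optional[float] = None,
) -> WorkforceResult:
    """Ceiling-division headcount: the smallest staff never understaffed."""
    if capacity <= 0:
        raise CapacityError("capacity must be positive")
    if annual_visits < 0:
        raise ValueError("annual visits must be non-negative")
    n = 0 if annual_visits == 0 else math.ceil(annual_visits / capacity)
    demand_minutes = (
        annual_visits * mean_visit_minutes if mean_visit_minutes is not None
        else float("nan")
    )
    return WorkforceResult(
        arm=arm if arm is not None else Arm.SOC,
        annual_capacity_visits_per_nurse=float(capacity),
        nurses_required=n,
        demand_minutes_per_year=demand_minutes,
    )
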