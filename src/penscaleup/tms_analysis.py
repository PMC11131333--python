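"""Time-and-motion summary statistics.

Computes the study-table-shaped summaries from validated observation
records: reported workday durations by cadre stratum, idle-time totals
and session durations split at noon, mean care minutes per patient
visit stratified by arm, condition class and visit type, per-worker
activity-group time shares, a one-way ANOVA arm comparison, and the
extrapolation of window-limited visit counts to full opening hours.

All interval summaries are normal-approximation means: mean ± 1.96·SE,
degenerating to a zero-width interval at n = 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tms_core import (
    ActivityEvent,
    ActivityGroup,
    Arm,
    Cadre,
    ConditionClass,
    FacilityRecord,
    HCWRecord,
    NOON_MIN,
    NURSING_CADRES,
    PatientVisit,
    VisitType,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ArmSummary",
    "ComparisonResult",
    "OVERALL",
    "workday_stats",
    "idle_stats",
    "time_per_patient_stats",
    "activity_proportions",
    "compare_arms",
    "extrapolate_visits",
    "UndefinedTestError",
    "UndefinedScaleError",
    "summaries_to_frame",
    "significance_stars",
]

#: Pseudo-arm label for rows pooling both arms.
OVERALL = "OVERALL"

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class UndefinedTestError(ValueError):
    """The arm-comparison test is undefined for the given groups."""


class UndefinedScaleError(ValueError):
    """No expected arrivals fall inside the observation window."""


@dataclass
class ArmSummary:
    """One summary cell: a statistic for one stratum in one arm."""

    statistic: str
    stratum: str
    arm: str                # Arm value or OVERALL
    n: int
    mean: float
    ci_low: float
    ci_high: float


@dataclass
class ComparisonResult:
    statistic: str
    group_labels: tuple[str, ...]
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int


def _mean_ci(values: Sequence[float]) -> tuple[int, float, float, float]:
    """n, mean and normal-approximation 95% CI; zero width for n = 1."""
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if n == 0:
        raise ValueError("empty stratum")
    mean = float(arr.mean())
    if n == 1:
        return 1, mean, mean, mean
    se = float(arr.std(ddof=1)) / math.sqrt(n)
    return n, mean, mean - Z95 * se, mean + Z95 * se


def _summaries(
    statistic: str,
    stratum: str,
    values_by_arm: Mapping[str, Sequence[float]],
) -> list[ArmSummary]:
    """Per-arm rows plus a pooled OVERALL row; empty strata are skipped."""
    rows: list[ArmSummary] = []
    pooled: list[float] = []
    for arm, values in values_by_arm.items():
        values = list(values)
        if not values:
            logger.warning("stratum %s/%s/%s is empty; omitted", statistic, stratum, arm)
            continue
        pooled.extend(values)
        n, m, lo, hi = _mean_ci(values)
        rows.append(ArmSummary(statistic, stratum, arm, n, m, lo, hi))
    if pooled:
        n, m, lo, hi = _mean_ci(pooled)
        rows.insert(0, ArmSummary(statistic, stratum, OVERALL, n, m, lo, hi))
    return rows


def _arm_map(facilities: Sequence[FacilityRecord]) -> dict[str, str]:
    return {f.facility_id: f.arm.value for f in facilities}


# ---------------------------------------------------------------------------
# workday durations
# ---------------------------------------------------------------------------

#: Cadre strata reported in the workday table.
WORKDAY_STRATA = ("ALL_STAFF", "NURSING_STAFF", "EXPERT_CLIENT", "OTHER_STAFF")


def workday_stats(
    hcws: Sequence[HCWRecord],
    facilities: Sequence[FacilityRecord],
) -> list[ArmSummary]:
    """Mean reported workday minutes per arm, for the four cadre strata:
    all staff, nursing staff, the expert client cadre, and everyone else."""
    arm_of = _arm_map(facilities)

    def in_stratum(h: HCWRecord, stratum: str) -> bool:
        if stratum == "ALL_STAFF":
            return True
        if stratum == "NURSING_STAFF":
            return h.cadre in NURSING_CADRES
        if stratum == "EXPERT_CLIENT":
            return h.cadre is Cadre.EXPERT_CLIENT
        return h.cadre not in NURSING_CADRES and h.cadre is not Cadre.EXPERT_CLIENT

    rows: list[ArmSummary] = []
    for stratum in WORKDAY_STRATA:
        by_arm: dict[str, list[float]] = {a.value: [] for a in Arm}
        for h in hcws:
            if in_stratum(h, stratum) and h.facility_id in arm_of:
                by_arm[arm_of[h.facility_id]].append(float(h.reported_workday_min))
        rows.extend(_summaries("workday_min", stratum, by_arm))
    return rows


# ---------------------------------------------------------------------------
# idle time
# ---------------------------------------------------------------------------

def idle_stats(
    events: Sequence[ActivityEvent],
    facilities: Sequence[FacilityRecord],
) -> list[ArmSummary]:
    """Idle-time summaries: total idle minutes per facility-day, and mean
    idle-session duration per HCW (overall and split at 12:00 by the
    session's start time)."""
    arm_of = _arm_map(facilities)
    idle = [e for e in events if e.category.group is ActivityGroup.IDLE_BREAK]

    rows: list[ArmSummary] = []

    # total idle minutes per facility-day (zero-idle days included)
    day_keys = {(e.facility_id, e.obs_date) for e in events}
    totals: dict[tuple[str, object], float] = {k: 0.0 for k in day_keys}
    for e in idle:
        totals[(e.facility_id, e.obs_date)] += e.duration_min
    by_arm: dict[str, list[float]] = {a.value: [] for a in Arm}
    for (fid, _), total in totals.items():
        if fid in arm_of:
            by_arm[arm_of[fid]].append(total)
    if day_keys:
        rows.extend(_summaries("idle_total_min_per_facility_day", "ALL", by_arm))

    # per-HCW mean session duration, overall and by daypart
    for stratum, keep in (
        ("ALL", lambda e: True),
        ("MORNING", lambda e: e.start_min < NOON_MIN),
        ("AFTERNOON", lambda e: e.start_min >= NOON_MIN),
    ):
        per_hcw: dict[str, list[float]] = {}
        for e in idle:
            if keep(e):
                per_hcw.setdefault(e.hcw_id, []).append(float(e.duration_min))
        by_arm = {a.value: [] for a in Arm}
        hcw_fac = {e.hcw_id: e.facility_id for e in events}
        for hcw_id, durs in per_hcw.items():
            fid = hcw_fac.get(hcw_id)
            if fid in arm_of:
                by_arm[arm_of[fid]].append(float(np.mean(durs)))
        if per_hcw:
            rows.extend(_summaries("idle_session_min_per_hcw", stratum, by_arm))
    return rows


# ---------------------------------------------------------------------------
# time per patient
# ---------------------------------------------------------------------------

#: Row structure of the time-per-patient table.
TIME_PER_PATIENT_STRATA: dict[str, tuple[Optional[ConditionClass], Optional[VisitType]]] = {
    "ALL": (None, None),
    "DM_HTN": (ConditionClass.DM_HTN, None),
    "NON_DM_HTN": (ConditionClass.NON_DM_HTN, None),
    "NEW": (None, VisitType.NEW),
    "FOLLOW_UP": (None, VisitType.FOLLOW_UP),
    "DM_HTN_NEW": (ConditionClass.DM_HTN, VisitType.NEW),
    "DM_HTN_FOLLOW_UP": (ConditionClass.DM_HTN, VisitType.FOLLOW_UP),
}


def time_per_patient_stats(
    visits: Sequence[PatientVisit],
    facilities: Sequence[FacilityRecord],
) -> list[ArmSummary]:
    """Mean care minutes per visit by arm × condition class × visit type."""
    arm_of = _arm_map(facilities)
    rows: list[ArmSummary] = []
    for stratum, (cond, vtype) in TIME_PER_PATIENT_STRATA.items():
        by_arm: dict[str, list[float]] = {a.value: [] for a in Arm}
        for v in visits:
            if cond is not None and v.condition_class is not cond:
                continue
            if vtype is not None and v.visit_type is not vtype:
                continue
            if v.facility_id in arm_of:
                by_arm[arm_of[v.facility_id]].append(float(v.duration_min))
        rows.extend(_summaries("time_per_patient_min", stratum, by_arm))
    return rows


# ---------------------------------------------------------------------------
# activity proportions
# ---------------------------------------------------------------------------

def activity_proportions(
    events: Sequence[ActivityEvent],
    facilities: Sequence[FacilityRecord],
) -> list[ArmSummary]:
    """Across-HCW mean share of observed minutes per activity group.

    Each HCW's own three shares sum to one; the reported cells average
    those per-HCW shares within each arm (so the three arm-level means
    generally do not sum to exactly 100%).  HCWs with zero observed
    minutes are excluded with a logged warning.
    """
    arm_of = _arm_map(facilities)
    minutes: dict[str, dict[ActivityGroup, float]] = {}
    hcw_fac: dict[str, str] = {}
    for e in events:
        d = minutes.setdefault(e.hcw_id, {g: 0.0 for g in ActivityGroup})
        d[e.category.group] += e.duration_min
        hcw_fac[e.hcw_id] = e.facility_id

    rows: list[ArmSummary] = []
    for group in ActivityGroup:
        by_arm: dict[str, list[float]] = {a.value: [] for a in Arm}
        for hcw_id, d in minutes.items():
            total = sum(d.values())
            if total <= 0:
                logger.warning("HCW %s has zero observed minutes; excluded", hcw_id)
                continue
            fid = hcw_fac[hcw_id]
            if fid in arm_of:
                by_arm[arm_of[fid]].append(d[group] / total)
        if any(by_arm.values()):
            rows.extend(_summaries("proportion_" + group.value.lower(), "ALL", by_arm))
    return rows


# ---------------------------------------------------------------------------
# arm comparison (one-way ANOVA)
# ---------------------------------------------------------------------------

def compare_arms(
    values: Sequence[float],
    labels: Sequence[str],
    statistic: str = "statistic",
) -> ComparisonResult:
    """One-way ANOVA across the label groups.

    With exactly two groups the F statistic equals the square of the
    pooled-variance two-sample t statistic.  Requires at least two
    groups with at least two observations each.
    """
    if len(values) != len(labels):
        raise ValueError("values and labels must align")
    groups: dict[str, list[float]] = {}
    for v, lab in zip(values, labels):
        groups.setdefault(str(lab), []).append(float(v))
    if len(groups) < 2:
        raise UndefinedTestError("need at least two groups")
    arrays = [np.asarray(g) for g in groups.values()]
    if any(a.size < 2 for a in arrays):
        raise UndefinedTestError("every group needs at least two observations")
    f, p = stats.f_oneway(*arrays)
    if math.isnan(f):  # all groups constant and equal: no evidence of difference
        f, p = 0.0, 1.0
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    return ComparisonResult(
        statistic=statistic,
        group_labels=tuple(groups),
        f_statistic=float(f),
        p_value=float(min(max(p, 0.0), 1.0)),
        df_between=k - 1,
        df_within=n_total - k,
    )


def significance_stars(p: float, thresholds: Sequence[tuple[float, str]] = (
    (0.001, "***"), (0.005, "**"),
)) -> str:
    """Star annotation at the thresholds used in the published tables."""
    for cut, stars in sorted(thresholds):
        if p < cut:
            return stars
    return ""


# ---------------------------------------------------------------------------
# extrapolation of observed visit counts to full opening hours
# ---------------------------------------------------------------------------

def _expected_arrivals(
    window: tuple[int, int],
    opening_hours: tuple[int, int],
    intensity_morning: float,
    intensity_afternoon: float,
) -> float:
    """Expected arrivals inside ``window`` under the two-piece intensity.

    The configured intensities are expected *totals* over the morning
    and afternoon portions of the opening hours; within each daypart the
    rate is uniform.
    """
    o_lo, o_hi = opening_hours
    w_lo, w_hi = window
    if not (o_lo <= w_lo < w_hi <= o_hi):
        raise ValueError("observation window must lie within opening hours")
    m_lo, m_hi = o_lo, min(NOON_MIN, o_hi)
    a_lo, a_hi = max(NOON_MIN, o_lo), o_hi
    expected = 0.0
    if m_hi > m_lo:
        overlap = max(0, min(w_hi, m_hi) - max(w_lo, m_lo))
        expected += intensity_morning * overlap / (m_hi - m_lo)
    if a_hi > a_lo:
        overlap = max(0, min(w_hi, a_hi) - max(w_lo, a_lo))
        expected += intensity_afternoon * overlap / (a_hi - a_lo)
    return expected


def extrapolate_visits(
    observed: pd.DataFrame,
    opening_hours: tuple[int, int],
    intensity_morning: float = 13.0,
    intensity_afternoon: float = 4.0,
) -> pd.DataFrame:
    """Scale window-limited visit counts up to full opening hours.

    ``observed`` needs columns ``facility_id``, ``arm``, ``obs_start_min``,
    ``obs_end_min`` and ``observed_visits`` (one row per facility-day).
    The estimate multiplies each observed count by the ratio of expected
    arrivals over the opening hours to expected arrivals in the observed
    window, under the two-piece morning/afternoon intensity; when the
    window covers the opening hours the estimate equals the observation.
    """
    required = {"facility_id", "arm", "obs_start_min", "obs_end_min", "observed_visits"}
    missing = required - set(observed.columns)
    if missing:
        raise ValueError(f"observed counts missing columns {sorted(missing)}")
    total_expected = _expected_arrivals(
        opening_hours, opening_hours, intensity_morning, intensity_afternoon)
    out = observed.copy()
    estimates = []
    for _, row in out.iterrows():
        window = (int(row["obs_start_min"]), int(row["obs_end_min"]))
        in_window = _expected_arrivals(
            window, opening_hours, intensity_morning, intensity_afternoon)
        if in_window <= 0:
            raise UndefinedScaleError(
                f"no expected arrivals inside window {window} for "
                f"facility {row['facility_id']}"
            )
        estimates.append(row["observed_visits"] * total_expected / in_window)
    out["estimated_visits"] = estimates
    out["estimated_visits_rounded"] = np.rint(out["estimated_visits"]).astype(int)
    return out


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def summaries_to_frame(rows: Sequence[ArmSummary]) -> pd.DataFrame:
    return pd.DataFrame({
        "statistic": [r.statistic for r in rows],
        "stratum": [r.stratum for r in rows],
        "arm": [r.arm for r in rows],
        "n": [r.n for r in rows],
        "mean": [r.mean for r in rows],
        "ci_low": [r.ci_low for r in rows],
        "ci_high": [r.ci_high for r in rows],
    })
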