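"""Core domain types and I/O for time-and-motion study (TMS) records.

A TMS observation campaign produces three kinds of records:

* activity events — one row per continuously observed healthcare-worker
  (HCW) activity interval, tagged with one of 19 activity codes that
  partition into three groups (patient care, administration/meetings,
  idle time/breaks);
* HCW records — one row per observed worker with cadre and the workday
  the worker reported;
* facility records — one row per primary healthcare clinic (PHC) with
  region, study arm, volume class and the observation window.

Times are integer minutes since midnight at one-minute granularity,
which is the resolution at which field observers record activities.
All three record kinds round-trip through a plain UTF-8 comma-separated
dialect with ISO dates and HH:MM clock times (one file per kind).
"""

from __future__ import annotations

import csv
import datetime
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityGroup",
    "ActivityCategory",
    "DEFAULT_VOCABULARY",
    "default_vocabulary",
    "Arm",
    "Region",
    "VolumeClass",
    "Cadre",
    "VisitType",
    "ConditionClass",
    "Daypart",
    "ActivityEvent",
    "HCWRecord",
    "FacilityRecord",
    "PatientVisit",
    "ValidationIssue",
    "ValidationReport",
    "validate_events",
    "group_visits",
    "parse_tms_csv",
    "write_tms_csv",
    "events_to_frame",
    "hcws_to_frame",
    "facilities_to_frame",
    "visits_to_frame",
    "SchemaError",
    "ParseError",
    "VocabularyError",
    "VisitConsistencyError",
    "MINUTES_PER_DAY",
    "NOON_MIN",
]

MINUTES_PER_DAY = 1440
#: Boundary between morning and afternoon: strictly before 12:00 is morning.
NOON_MIN = 720


class SchemaError(ValueError):
    """A CSV file is missing a required column."""


class ParseError(ValueError):
    """One or more rows of a CSV file could not be parsed.

    Carries a row-indexed report in :attr:`row_errors` as a list of
    ``(filename, row_number, message)`` tuples (row numbers are 1-based
    and include the header row).
    """

    def __init__(self, row_errors: Sequence[tuple[str, int, str]]):
        self.row_errors = list(row_errors)
        lines = [f"{f}:{r}: {m}" for f, r, m in self.row_errors[:20]]
        more = len(self.row_errors) - len(lines)
        if more > 0:
            lines.append(f"... and {more} more")
        super().__init__("row-level parse errors:\n" + "\n".join(lines))


class VocabularyError(ValueError):
    """An activity code is not part of the configured vocabulary."""


class VisitConsistencyError(ValueError):
    """A patient's care events carry conflicting visit attributes."""


class ActivityGroup(str, Enum):
    PATIENT_CARE = "PATIENT_CARE"
    ADMIN_MEETING = "ADMIN_MEETING"
    IDLE_BREAK = "IDLE_BREAK"


@dataclass(frozen=True)
class ActivityCategory:
    """One of the 19 activity codes together with its group."""

    code: str
    group: ActivityGroup


# Default 19-code vocabulary.  The field tool distinguishes 19 activities
# across the three groups; the study instrument's exact code list is not
# published, so this is a documented stand-in with the same structure
# (10 care, 4 administrative, 5 idle/break codes).  It is configurable:
# every parsing entry point accepts an alternative ``vocabulary`` mapping.
_DEFAULT_CODES: dict[str, ActivityGroup] = {
    # patient care
    "REGISTRATION": ActivityGroup.PATIENT_CARE,
    "TRIAGE": ActivityGroup.PATIENT_CARE,
    "VITALS": ActivityGroup.PATIENT_CARE,
    "SCREENING": ActivityGroup.PATIENT_CARE,
    "CONSULTATION": ActivityGroup.PATIENT_CARE,
    "COUNSELLING": ActivityGroup.PATIENT_CARE,
    "BLOOD_DRAW": ActivityGroup.PATIENT_CARE,
    "DISPENSING": ActivityGroup.PATIENT_CARE,
    "HEALTH_EDUCATION": ActivityGroup.PATIENT_CARE,
    "REFERRAL": ActivityGroup.PATIENT_CARE,
    # administration / meetings
    "ADMIN": ActivityGroup.ADMIN_MEETING,
    "MEETING": ActivityGroup.ADMIN_MEETING,
    "REPORTING": ActivityGroup.ADMIN_MEETING,
    "STOCK_MANAGEMENT": ActivityGroup.ADMIN_MEETING,
    # idle time / breaks
    "IDLE": ActivityGroup.IDLE_BREAK,
    "LUNCH_BREAK": ActivityGroup.IDLE_BREAK,
    "TEA_BREAK": ActivityGroup.IDLE_BREAK,
    "CLEANING": ActivityGroup.IDLE_BREAK,
    "PERSONAL": ActivityGroup.IDLE_BREAK,
}

DEFAULT_VOCABULARY: Mapping[str, ActivityCategory] = {
    code: ActivityCategory(code, group) for code, group in _DEFAULT_CODES.items()
}


def default_vocabulary() -> dict[str, ActivityCategory]:
    """Return a fresh copy of the default 19-code activity vocabulary."""
    return dict(DEFAULT_VOCABULARY)


class Arm(str, Enum):
    SOC = "SOC"
    INTERVENTION = "INTERVENTION"


class Region(str, Enum):
    HHOHHO = "HHOHHO"
    LUBOMBO = "LUBOMBO"
    SHISELWENI = "SHISELWENI"
    MANZINI = "MANZINI"


class VolumeClass(str, Enum):
    LOW = "LOW"   # clinics expecting fewer than 100 patients a day
    HIGH = "HIGH"


class Cadre(str, Enum):
    GENERAL_NURSE = "GENERAL_NURSE"
    NURSING_SISTER = "NURSING_SISTER"
    NURSE_ASSISTANT = "NURSE_ASSISTANT"
    EXPERT_CLIENT = "EXPERT_CLIENT"
    OTHER = "OTHER"


#: Cadres counted as "nursing staff" in workday summaries (the expert
#: client is a distinct lay cadre and is reported separately).
NURSING_CADRES = frozenset(
    {Cadre.GENERAL_NURSE, Cadre.NURSING_SISTER, Cadre.NURSE_ASSISTANT}
)


class VisitType(str, Enum):
    NEW = "NEW"
    FOLLOW_UP = "FOLLOW_UP"


class ConditionClass(str, Enum):
    DM_HTN = "DM_HTN"
    NON_DM_HTN = "NON_DM_HTN"


class Daypart(str, Enum):
    MORNING = "MORNING"
    AFTERNOON = "AFTERNOON"


def daypart_of(start_min: int) -> Daypart:
    """Daypart of an interval, by its start: strictly before 12:00 is morning."""
    return Daypart.MORNING if start_min < NOON_MIN else Daypart.AFTERNOON


@dataclass
class ActivityEvent:
    """One continuously observed HCW activity interval.

    Patient attributes (``patient_id`` and the three flags) must be
    present exactly when the category belongs to the patient-care group;
    :func:`validate_events` reports violations rather than raising.
    """

    facility_id: str
    hcw_id: str
    obs_date: datetime.date
    start_min: int
    end_min: int
    category: ActivityCategory
    patient_id: Optional[str] = None
    is_new_visit: Optional[bool] = None
    is_dm_htn: Optional[bool] = None
    is_hiv_comorbid: Optional[bool] = None

    @property
    def duration_min(self) -> int:
        return self.end_min - self.start_min


@dataclass
class HCWRecord:
    hcw_id: str
    facility_id: str
    cadre: Cadre
    reported_start_min: int
    reported_end_min: int

    @property
    def reported_workday_min(self) -> int:
        return self.reported_end_min - self.reported_start_min


@dataclass
class FacilityRecord:
    facility_id: str
    region: Region
    arm: Arm
    volume_class: VolumeClass
    n_staff_present: int
    observation_window: tuple[int, int]


@dataclass
class PatientVisit:
    """A per-patient care episode: all care activities for one patient on
    one date at one facility, merged even if non-contiguous."""

    patient_id: str
    facility_id: str
    hcw_id: str
    obs_date: datetime.date
    start_min: int
    end_min: int
    duration_min: int
    visit_type: VisitType
    condition_class: ConditionClass
    daypart: Daypart
    is_hiv_comorbid: bool = False


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationIssue:
    kind: str               # "time_order" | "time_range" | "flags" | "overlap"
    message: str
    event_indices: tuple[int, ...]


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __len__(self) -> int:
        return len(self.issues)


def validate_events(events: Sequence[ActivityEvent]) -> ValidationReport:
    """Check every event-level invariant; violations are data, not exceptions.

    Checks, per event: ``end_min > start_min``; ``0 <= start_min < 1440``
    and ``end_min <= 1440``; patient attributes present iff the activity
    is patient care.  Across events: no two events of the same HCW on the
    same date overlap in time.
    """
    report = ValidationReport()
    by_hcw_day: dict[tuple[str, datetime.date], list[int]] = defaultdict(list)
    for i, ev in enumerate(events):
        if ev.end_min <= ev.start_min:
            report.issues.append(ValidationIssue(
                "time_order",
                f"event {i}: end_min {ev.end_min} not after start_min {ev.start_min}",
                (i,),
            ))
        if not (0 <= ev.start_min < MINUTES_PER_DAY) or ev.end_min > MINUTES_PER_DAY:
            report.issues.append(ValidationIssue(
                "time_range",
                f"event {i}: interval [{ev.start_min}, {ev.end_min}) outside the day",
                (i,),
            ))
        is_care = ev.category.group is ActivityGroup.PATIENT_CARE
        has_patient = (
            ev.patient_id is not None
            and ev.is_new_visit is not None
            and ev.is_dm_htn is not None
            and ev.is_hiv_comorbid is not None
        )
        any_patient = (
            ev.patient_id is not None
            or ev.is_new_visit is not None
            or ev.is_dm_htn is not None
            or ev.is_hiv_comorbid is not None
        )
        if is_care and not has_patient:
            report.issues.append(ValidationIssue(
                "flags",
                f"event {i}: patient-care event missing patient attributes",
                (i,),
            ))
        if not is_care and any_patient:
            report.issues.append(ValidationIssue(
                "flags",
                f"event {i}: non-care event ({ev.category.code}) carries patient attributes",
                (i,),
            ))
        by_hcw_day[(ev.hcw_id, ev.obs_date)].append(i)

    for (hcw_id, day), idxs in by_hcw_day.items():
        ordered = sorted(idxs, key=lambda i: (events[i].start_min, events[i].end_min))
        for a, b in zip(ordered, ordered[1:]):
            if events[b].start_min < events[a].end_min:
                report.issues.append(ValidationIssue(
                    "overlap",
                    f"events {a} and {b} overlap for HCW {hcw_id} on {day}",
                    (a, b),
                ))
    return report


# ---------------------------------------------------------------------------
# grouping care activities into per-patient visits
# ---------------------------------------------------------------------------

def group_visits(events: Sequence[ActivityEvent]) -> list[PatientVisit]:
    """Group patient-care events into one visit per (patient, facility, date).

    The visit duration is the sum of the grouped events' durations, so
    total care minutes are conserved exactly.  All of a patient's care
    events on one date merge into a single visit even when they are not
    contiguous; a patient seen on two dates yields two visits.  The
    attending HCW recorded on the visit is the one of the earliest event.

    Raises :class:`VisitConsistencyError` if one patient's events carry
    conflicting ``is_new_visit`` / ``is_dm_htn`` / ``is_hiv_comorbid``
    flags.
    """
    groups: dict[tuple[str, str, datetime.date], list[ActivityEvent]] = defaultdict(list)
    for ev in events:
        if ev.category.group is not ActivityGroup.PATIENT_CARE:
            continue
        if ev.patient_id is None:
            raise VisitConsistencyError(
                "patient-care event without patient_id; run validate_events first"
            )
        groups[(ev.patient_id, ev.facility_id, ev.obs_date)].append(ev)

    visits: list[PatientVisit] = []
    for (patient_id, facility_id, day), evs in groups.items():
        for flag in ("is_new_visit", "is_dm_htn", "is_hiv_comorbid"):
            values = {getattr(e, flag) for e in evs}
            if len(values) > 1:
                raise VisitConsistencyError(
                    f"patient {patient_id} on {day}: conflicting {flag} values {values}"
                )
        evs.sort(key=lambda e: e.start_min)
        first = evs[0]
        start = first.start_min
        visits.append(PatientVisit(
            patient_id=patient_id,
            facility_id=facility_id,
            hcw_id=first.hcw_id,
            obs_date=day,
            start_min=start,
            end_min=max(e.end_min for e in evs),
            duration_min=sum(e.duration_min for e in evs),
            visit_type=VisitType.NEW if first.is_new_visit else VisitType.FOLLOW_UP,
            condition_class=(
                ConditionClass.DM_HTN if first.is_dm_htn else ConditionClass.NON_DM_HTN
            ),
            daypart=daypart_of(start),
            is_hiv_comorbid=bool(first.is_hiv_comorbid),
        ))
    visits.sort(key=lambda v: (v.facility_id, v.obs_date, v.start_min, v.patient_id))
    return visits


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

EVENTS_FILENAME = "tms_events.csv"
HCWS_FILENAME = "tms_hcws.csv"
FACILITIES_FILENAME = "tms_facilities.csv"

_EVENT_COLUMNS = [
    "facility_id", "hcw_id", "date", "start", "end", "activity_code",
    "patient_id", "is_new_visit", "is_dm_htn", "is_hiv_comorbid",
]
_HCW_COLUMNS = ["hcw_id", "facility_id", "cadre", "reported_start", "reported_end"]
_FACILITY_COLUMNS = [
    "facility_id", "region", "arm", "volume_class", "n_staff_present",
    "obs_start", "obs_end",
]


def _minutes_to_hhmm(m: int) -> str:
    return f"{m // 60:02d}:{m % 60:02d}"


def _hhmm_to_minutes(text: str) -> int:
    parts = text.strip().split(":")
    if len(parts) != 2:
        raise ValueError(f"clock time {text!r} is not HH:MM")
    h, m = int(parts[0]), int(parts[1])
    if not (0 <= h <= 24 and 0 <= m < 60):
        raise ValueError(f"clock time {text!r} out of range")
    return h * 60 + m


def _bool_to_csv(v: Optional[bool]) -> str:
    if v is None:
        return ""
    return "true" if v else "false"


def _csv_to_bool(text: str) -> Optional[bool]:
    t = text.strip().lower()
    if t == "":
        return None
    if t in {"true", "1", "yes"}:
        return True
    if t in {"false", "0", "no"}:
        return False
    raise ValueError(f"boolean flag {text!r} not understood")


def write_tms_csv(
    events: Iterable[ActivityEvent],
    hcws: Iterable[HCWRecord],
    facilities: Iterable[FacilityRecord],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the three canonical CSV files into ``out_dir``; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "events": out / EVENTS_FILENAME,
        "hcws": out / HCWS_FILENAME,
        "facilities": out / FACILITIES_FILENAME,
    }
    with paths["events"].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_EVENT_COLUMNS)
        for ev in events:
            w.writerow([
                ev.facility_id, ev.hcw_id, ev.obs_date.isoformat(),
                _minutes_to_hhmm(ev.start_min), _minutes_to_hhmm(ev.end_min),
                ev.category.code,
                ev.patient_id or "",
                _bool_to_csv(ev.is_new_visit),
                _bool_to_csv(ev.is_dm_htn),
                _bool_to_csv(ev.is_hiv_comorbid),
            ])
    with paths["hcws"].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_HCW_COLUMNS)
        for h in hcws:
            w.writerow([
                h.hcw_id, h.facility_id, h.cadre.value,
                _minutes_to_hhmm(h.reported_start_min),
                _minutes_to_hhmm(h.reported_end_min),
            ])
    with paths["facilities"].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_FACILITY_COLUMNS)
        for f in facilities:
            w.writerow([
                f.facility_id, f.region.value, f.arm.value, f.volume_class.value,
                f.n_staff_present,
                _minutes_to_hhmm(f.observation_window[0]),
                _minutes_to_hhmm(f.observation_window[1]),
            ])
    return paths


def _check_header(name: str, header: Sequence[str], expected: Sequence[str]) -> None:
    missing = [c for c in expected if c not in header]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {', '.join(missing)}")


def parse_tms_csv(
    path: str | Path,
    vocabulary: Mapping[str, ActivityCategory] | None = None,
) -> tuple[list[ActivityEvent], list[HCWRecord], list[FacilityRecord]]:
    """Read a TMS bundle from ``path`` (a directory holding the three
    canonical CSV files, or the events file itself with siblings).

    Clock times are converted to minutes since midnight.  A missing
    column raises :class:`SchemaError` naming the column; rows that fail
    to parse are collected into a row-indexed :class:`ParseError`; an
    activity code outside the vocabulary raises
    :class:`VocabularyError`.
    """
    vocabulary = dict(vocabulary) if vocabulary is not None else default_vocabulary()
    p = Path(path)
    base = p if p.is_dir() else p.parent
    ev_path = base / EVENTS_FILENAME
    hcw_path = base / HCWS_FILENAME
    fac_path = base / FACILITIES_FILENAME
    for f in (ev_path, hcw_path, fac_path):
        if not f.exists():
            raise FileNotFoundError(f)

    row_errors: list[tuple[str, int, str]] = []
    events: list[ActivityEvent] = []
    with ev_path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(ev_path.name, reader.fieldnames or [], _EVENT_COLUMNS)
        for lineno, row in enumerate(reader, start=2):
            code = row["activity_code"].strip()
            if code not in vocabulary:
                raise VocabularyError(
                    f"{ev_path.name}:{lineno}: unknown activity code {code!r}"
                )
            try:
                events.append(ActivityEvent(
                    facility_id=row["facility_id"].strip(),
                    hcw_id=row["hcw_id"].strip(),
                    obs_date=datetime.date.fromisoformat(row["date"].strip()),
                    start_min=_hhmm_to_minutes(row["start"]),
                    end_min=_hhmm_to_minutes(row["end"]),
                    category=vocabulary[code],
                    patient_id=row["patient_id"].strip() or None,
                    is_new_visit=_csv_to_bool(row["is_new_visit"]),
                    is_dm_htn=_csv_to_bool(row["is_dm_htn"]),
                    is_hiv_comorbid=_csv_to_bool(row["is_hiv_comorbid"]),
                ))
            except ValueError as exc:
                row_errors.append((ev_path.name, lineno, str(exc)))

    hcws: list[HCWRecord] = []
    with hcw_path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(hcw_path.name, reader.fieldnames or [], _HCW_COLUMNS)
        for lineno, row in enumerate(reader, start=2):
            try:
                hcws.append(HCWRecord(
                    hcw_id=row["hcw_id"].strip(),
                    facility_id=row["facility_id"].strip(),
                    cadre=Cadre(row["cadre"].strip()),
                    reported_start_min=_hhmm_to_minutes(row["reported_start"]),
                    reported_end_min=_hhmm_to_minutes(row["reported_end"]),
                ))
            except ValueError as exc:
                row_errors.append((hcw_path.name, lineno, str(exc)))

    facilities: list[FacilityRecord] = []
    with fac_path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(fac_path.name, reader.fieldnames or [], _FACILITY_COLUMNS)
        for lineno, row in enumerate(reader, start=2):
            try:
                facilities.append(FacilityRecord(
                    facility_id=row["facility_id"].strip(),
                    region=Region(row["region"].strip()),
                    arm=Arm(row["arm"].strip()),
                    volume_class=VolumeClass(row["volume_class"].strip()),
                    n_staff_present=int(row["n_staff_present"]),
                    observation_window=(
                        _hhmm_to_minutes(row["obs_start"]),
                        _hhmm_to_minutes(row["obs_end"]),
                    ),
                ))
            except ValueError as exc:
                row_errors.append((fac_path.name, lineno, str(exc)))

    if row_errors:
        raise ParseError(row_errors)
    return events, hcws, facilities


# ---------------------------------------------------------------------------
# DataFrame views (analysis layers work on these)
# ---------------------------------------------------------------------------

def events_to_frame(events: Sequence[ActivityEvent]) -> pd.DataFrame:
    return pd.DataFrame({
        "facility_id": [e.facility_id for e in events],
        "hcw_id": [e.hcw_id for e in events],
        "obs_date": [e.obs_date for e in events],
        "start_min": [e.start_min for e in events],
        "end_min": [e.end_min for e in events],
        "duration_min": [e.duration_min for e in events],
        "activity_code": [e.category.code for e in events],
        "group": [e.category.group.value for e in events],
        "patient_id": [e.patient_id for e in events],
    })


def hcws_to_frame(hcws: Sequence[HCWRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "hcw_id": [h.hcw_id for h in hcws],
        "facility_id": [h.facility_id for h in hcws],
        "cadre": [h.cadre.value for h in hcws],
        "reported_start_min": [h.reported_start_min for h in hcws],
        "reported_end_min": [h.reported_end_min for h in hcws],
        "reported_workday_min": [h.reported_workday_min for h in hcws],
    })


def facilities_to_frame(facilities: Sequence[FacilityRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "facility_id": [f.facility_id for f in facilities],
        "region": [f.region.value for f in facilities],
        "arm": [f.arm.value for f in facilities],
        "volume_class": [f.volume_class.value for f in facilities],
        "n_staff_present": [f.n_staff_present for f in facilities],
        "obs_start_min": [f.observation_window[0] for f in facilities],
        "obs_end_min": [f.observation_window[1] for f in facilities],
    })


def visits_to_frame(visits: Sequence[PatientVisit]) -> pd.DataFrame:
    return pd.DataFrame({
        "patient_id": [v.patient_id for v in visits],
        "facility_id": [v.facility_id for v in visits],
        "hcw_id": [v.hcw_id for v in visits],
        "obs_date": [v.obs_date for v in visits],
        "start_min": [v.start_min for v in visits],
        "end_min": [v.end_min for v in visits],
        "duration_min": [v.duration_min for v in visits],
        "visit_type": [v.visit_type.value for v in visits],
        "condition_class": [v.condition_class.value for v in visits],
        "daypart": [v.daypart.value for v in visits],
        "is_hiv_comorbid": [v.is_hiv_comorbid for v in visits],
    })
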