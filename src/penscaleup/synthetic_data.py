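"""Synthetic generator for TMS observation records.

The generator emulates the observation protocol of the field study this
package models: 28 randomly selected primary healthcare clinics, each
visited twice; on each visit day observers shadow a small number of
nurses continuously, logging per-patient care episodes, idle/break
sessions and administrative sessions at one-minute resolution, while
each observed worker also self-reports their workday.

Statistical structure, with defaults calibrated to the study's printed
summaries:

* patient arrivals: a two-piece (morning/afternoon) homogeneous Poisson
  process per facility-day, defaults 13 morning and 4 afternoon
  arrivals, which produces the documented morning peak;
* patient mix: Bernoulli condition class (DM/HTN share 353/1171),
  Bernoulli visit type (6% of DM/HTN visits are new; the new-visit
  share for other patients is a modelling default), and an HIV
  comorbidity flag among DM/HTN patients;
* service times: gamma distributed, positive and right-skewed, with the
  configured (arm, condition class, visit type) mean and a common
  coefficient of variation;
* idle/break sessions: at most one per daypart per shadowed nurse,
  gamma distributed with (arm, daypart)-specific means; administrative
  sessions occur with a fixed probability;
* workdays: normal around the arm mean (497 min standard of care,
  516 min intervention).

Randomness is drawn from independent substreams per facility-day
(``SeedSequence`` spawn keys), so changing the facility count never
perturbs the records generated for other facilities.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .tms_core import (
    ActivityEvent,
    Arm,
    Cadre,
    ConditionClass,
    Daypart,
    FacilityRecord,
    HCWRecord,
    MINUTES_PER_DAY,
    NOON_MIN,
    Region,
    VisitType,
    VolumeClass,
    default_vocabulary,
    write_tms_csv,
)

__all__ = [
    "GeneratorParams",
    "default_params",
    "GenerationError",
    "StudyBundle",
    "generate_facility_day",
    "generate_study",
    "make_facility",
]


class GenerationError(RuntimeError):
    """The configured load cannot be scheduled within the day."""


def _default_service_time_means() -> dict[tuple[Arm, ConditionClass, VisitType], float]:
    """Mean per-visit care minutes by arm, condition class and visit type.

    DM/HTN strata are the published stratified means (new 16.7/11.0,
    follow-up 10.2/8.7 minutes for standard-of-care/intervention).  For
    non-DM/HTN patients only the class means (9.6 and 8.2 min) and the
    all-patient new-visit means (11.0 and 9.6 min) are published; the
    follow-up means below are solved so that, at the default new-visit
    share for this class, the class mean is reproduced exactly.
    """
    S, I = Arm.SOC, Arm.INTERVENTION
    D, N = ConditionClass.DM_HTN, ConditionClass.NON_DM_HTN
    NEW, FU = VisitType.NEW, VisitType.FOLLOW_UP
    return {
        (S, D, NEW): 16.7, (S, D, FU): 10.2,
        (I, D, NEW): 11.0, (I, D, FU): 8.7,
        (S, N, NEW): 11.0, (S, N, FU): 9.25,
        (I, N, NEW): 9.6, (I, N, FU): 7.85,
    }


def _default_idle_session_means() -> dict[tuple[Arm, Daypart], float]:
    # Published mean idle-session durations: mornings 24/23 min and
    # afternoons 45/40 min (standard of care / intervention).
    return {
        (Arm.SOC, Daypart.MORNING): 24.0,
        (Arm.SOC, Daypart.AFTERNOON): 45.0,
        (Arm.INTERVENTION, Daypart.MORNING): 23.0,
        (Arm.INTERVENTION, Daypart.AFTERNOON): 40.0,
    }


@dataclass
class GeneratorParams:
    """All knobs of the synthetic study, calibrated to the published study."""

    n_facilities: int = 28
    arm_split: float = 0.5                 # fraction of facilities on intervention
    region_weights: dict[Region, float] = field(default_factory=lambda: {
        Region.HHOHHO: 0.25, Region.LUBOMBO: 0.25,
        Region.SHISELWENI: 0.25, Region.MANZINI: 0.25,
    })
    low_volume_fraction: float = 20 / 28
    nurses_per_facility: float = 4.0       # mean nursing headcount per clinic
    staff_per_facility: float = 12.0       # mean total staff present
    visits_per_facility: int = 2           # each clinic observed on two dates
    shadowed_nurses_per_day: int = 2       # nurses continuously observed per day

    # arrivals: expected patients per facility per daypart
    arrival_intensity_morning: float = 13.0
    arrival_intensity_afternoon: float = 4.0
    opening_start_min: int = 480           # clinics open 08:00
    opening_end_min: int = 960             # and close 16:00

    # patient mix
    dm_htn_share: float = 353 / 1171
    new_visit_share_dm_htn: float = 0.06   # 94% of DM/HTN visits are follow-ups
    new_visit_share_other: float = 0.20    # modelling default, unpublished
    hiv_comorbid_share_dm_htn: float = 23 / 353

    # service and session durations (minutes)
    service_time_means: dict[tuple[Arm, ConditionClass, VisitType], float] = field(
        default_factory=_default_service_time_means)
    service_time_cv: float = 0.5
    idle_session_mean_min: dict[tuple[Arm, Daypart], float] = field(
        default_factory=_default_idle_session_means)
    idle_session_cv: float = 0.5
    idle_session_prob_morning: float = 0.45
    idle_session_prob_afternoon: float = 0.45
    admin_session_prob: float = 0.25
    admin_session_mean_min: float = 15.0

    # reported workdays (minutes)
    workday_mean_min: dict[Arm, float] = field(default_factory=lambda: {
        Arm.SOC: 497.0, Arm.INTERVENTION: 516.0,
    })
    workday_sd_min: float = 35.0
    workday_start_mean_min: float = 478.0
    workday_start_sd_min: float = 10.0

    start_date: datetime.date = datetime.date(2022, 6, 20)
    seed: int = 20220620

    def validate(self) -> None:
        probs = [
            self.arm_split, self.low_volume_fraction, self.dm_htn_share,
            self.new_visit_share_dm_htn, self.new_visit_share_other,
            self.hiv_comorbid_share_dm_htn, self.idle_session_prob_morning,
            self.idle_session_prob_afternoon, self.admin_session_prob,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        means = (
            list(self.service_time_means.values())
            + list(self.idle_session_mean_min.values())
            + list(self.workday_mean_min.values())
            + [self.admin_session_mean_min]
        )
        if any(m <= 0 for m in means):
            raise ValueError("all duration means must be positive")
        if self.arrival_intensity_morning < 0 or self.arrival_intensity_afternoon < 0:
            raise ValueError("arrival intensities must be non-negative")
        if self.n_facilities < 1 or self.shadowed_nurses_per_day < 1:
            raise ValueError("facility and shadowed-nurse counts must be >= 1")


def default_params() -> GeneratorParams:
    """The study-calibrated defaults (28 clinics, two visits each, ...)."""
    return GeneratorParams()


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

_VOCAB = default_vocabulary()
_CARE_CODE = _VOCAB["CONSULTATION"]
_IDLE_CODE = _VOCAB["IDLE"]
_ADMIN_CODE = _VOCAB["ADMIN"]


def _gamma_minutes(rng: np.random.Generator, mean: float, cv: float) -> int:
    """Positive integer-minute duration from a gamma(mean, cv) law.

    Discretisation uses stochastic rounding (floor plus a Bernoulli unit
    on the fractional part) so the integer durations keep the configured
    mean exactly, unlike round-to-nearest which is slightly biased for a
    skewed law at one-minute granularity.
    """
    if cv <= 0:
        draw = mean
    else:
        shape = 1.0 / cv**2
        draw = rng.gamma(shape, mean / shape)
    base = int(np.floor(draw))
    if rng.random() < draw - base:
        base += 1
    return max(1, base)


def make_facility(
    index: int,
    params: GeneratorParams,
    rng: Optional[np.random.Generator] = None,
) -> FacilityRecord:
    """Deterministic facility roster entry for position ``index``.

    Arms, regions and volume classes follow quota sequences (largest
    remainder) so that any prefix of the facility list is close to the
    configured split (the study balanced arms and regions by design)
    and a facility's assignment never depends on the total count.
    """

    def quota(i: int, frac: float) -> bool:
        return math.floor((i + 1) * frac) - math.floor(i * frac) == 1

    arm = Arm.INTERVENTION if quota(index, params.arm_split) else Arm.SOC
    regions = list(params.region_weights)
    region = regions[index % len(regions)]
    # volume classes balanced within arms, as in the sampling design
    arm_index = sum(
        1 for j in range(index)
        if (Arm.INTERVENTION if quota(j, params.arm_split) else Arm.SOC) is arm
    )
    volume = (VolumeClass.LOW if quota(arm_index, params.low_volume_fraction)
              else VolumeClass.HIGH)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(0, index)))
    n_staff = max(
        int(np.ceil(params.nurses_per_facility)),
        int(rng.poisson(params.staff_per_facility)),
    )
    return FacilityRecord(
        facility_id=f"F{index + 1:03d}",
        region=region,
        arm=arm,
        volume_class=volume,
        n_staff_present=n_staff,
        observation_window=(params.opening_start_min, params.opening_end_min),
    )


def _facility_roster(
    facility: FacilityRecord,
    params: GeneratorParams,
    rng: np.random.Generator,
) -> list[HCWRecord]:
    """Staff roster: nursing cadres first, then other staff to the total."""
    n_nurses = max(params.shadowed_nurses_per_day, int(rng.poisson(params.nurses_per_facility)))
    n_total = max(n_nurses, facility.n_staff_present)
    cadres = [Cadre.GENERAL_NURSE, Cadre.NURSING_SISTER, Cadre.NURSE_ASSISTANT]
    roster: list[HCWRecord] = []
    workday_mean = params.workday_mean_min[facility.arm]
    for j in range(n_total):
        if j < n_nurses:
            cadre = cadres[j % len(cadres)]
        elif j == n_nurses:
            cadre = Cadre.EXPERT_CLIENT
        else:
            cadre = Cadre.OTHER
        start = int(round(rng.normal(params.workday_start_mean_min,
                                     params.workday_start_sd_min)))
        start = min(max(start, 0), NOON_MIN - 1)
        length = int(round(rng.normal(workday_mean, params.workday_sd_min)))
        length = max(60, length)
        end = min(start + length, MINUTES_PER_DAY - 1)
        roster.append(HCWRecord(
            hcw_id=f"{facility.facility_id}-H{j + 1:02d}",
            facility_id=facility.facility_id,
            cadre=cadre,
            reported_start_min=start,
            reported_end_min=end,
        ))
    return roster


@dataclass
class _Job:
    nominal_min: float
    kind: str                       # "care" | "idle" | "admin"
    patient_id: Optional[str] = None
    condition: Optional[ConditionClass] = None
    visit_type: Optional[VisitType] = None
    hiv: bool = False
    duration: Optional[int] = None  # pre-drawn for care jobs


def generate_facility_day(
    facility: FacilityRecord,
    params: GeneratorParams,
    seed: int,
    hcws: Optional[Sequence[HCWRecord]] = None,
    obs_date: Optional[datetime.date] = None,
) -> list[ActivityEvent]:
    """Simulate one observation day at one facility.

    Arrivals are drawn from the two-piece Poisson process; each patient
    gets a condition class, visit type and gamma service time; patients
    are dispatched to the least-busy shadowed nurse; idle and admin
    sessions are interleaved at planned break slots, delaying later
    services (patients queue) so that events never overlap.  Raises
    :class:`GenerationError` when the demanded care minutes cannot fit
    into the day for the shadowed staff.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    if obs_date is None:
        obs_date = params.start_date
    if hcws is None:
        hcws = _facility_roster(facility, params, rng)
    nurses = [h for h in hcws if h.cadre in {
        Cadre.GENERAL_NURSE, Cadre.NURSING_SISTER, Cadre.NURSE_ASSISTANT,
    }]
    shadowed = nurses[: params.shadowed_nurses_per_day]
    if not shadowed:
        raise GenerationError("no nursing staff available to shadow")

    arm = facility.arm
    open_start, open_end = params.opening_start_min, params.opening_end_min
    morning_span = (open_start, min(NOON_MIN, open_end))
    afternoon_span = (max(NOON_MIN, open_start), open_end)

    # --- facility-level arrivals ------------------------------------------
    arrivals: list[tuple[float, ConditionClass, VisitType, bool]] = []
    for (lo, hi), lam in (
        (morning_span, params.arrival_intensity_morning),
        (afternoon_span, params.arrival_intensity_afternoon),
    ):
        if hi <= lo or lam <= 0:
            continue
        n = rng.poisson(lam)
        times = np.sort(rng.uniform(lo, hi, size=n))
        for t in times:
            dm = rng.random() < params.dm_htn_share
            cond = ConditionClass.DM_HTN if dm else ConditionClass.NON_DM_HTN
            new_share = (params.new_visit_share_dm_htn if dm
                         else params.new_visit_share_other)
            vtype = VisitType.NEW if rng.random() < new_share else VisitType.FOLLOW_UP
            hiv = dm and rng.random() < params.hiv_comorbid_share_dm_htn
            arrivals.append((float(t), cond, vtype, hiv))

    # feasibility: expected care demand vs shadowed staffed minutes
    demanded = sum(
        params.service_time_means[(arm, cond, vtype)]
        for _, cond, vtype, _ in arrivals
    )
    staffed = len(shadowed) * (MINUTES_PER_DAY - open_start)
    if demanded > staffed:
        raise GenerationError(
            f"care demand of {demanded:.0f} min exceeds {staffed} staffed minutes; "
            "increase shadowed staff or lower the arrival intensity"
        )

    # --- dispatch arrivals to the least-busy nurse ------------------------
    per_nurse_jobs: dict[str, list[_Job]] = {h.hcw_id: [] for h in shadowed}
    load = {h.hcw_id: 0.0 for h in shadowed}
    for k, (t, cond, vtype, hiv) in enumerate(arrivals):
        nurse = min(shadowed, key=lambda h: (load[h.hcw_id], h.hcw_id))
        dur = _gamma_minutes(rng, params.service_time_means[(arm, cond, vtype)],
                             params.service_time_cv)
        load[nurse.hcw_id] += dur
        per_nurse_jobs[nurse.hcw_id].append(_Job(
            nominal_min=t, kind="care",
            patient_id=f"{facility.facility_id}-{obs_date.isoformat()}-P{k + 1:03d}",
            condition=cond, visit_type=vtype, hiv=hiv, duration=dur,
        ))

    # --- planned break/admin slots per nurse ------------------------------
    for nurse in shadowed:
        jobs = per_nurse_jobs[nurse.hcw_id]
        if rng.random() < params.idle_session_prob_morning:
            jobs.append(_Job(nominal_min=rng.uniform(600, 690), kind="idle"))
        if rng.random() < params.idle_session_prob_afternoon:
            jobs.append(_Job(nominal_min=rng.uniform(780, 870), kind="idle"))
        if rng.random() < params.admin_session_prob:
            jobs.append(_Job(nominal_min=rng.uniform(open_start, open_end), kind="admin"))
        jobs.sort(key=lambda j: j.nominal_min)

    # --- build each nurse's activity log ----------------------------------
    events: list[ActivityEvent] = []
    for nurse in shadowed:
        cursor = float(nurse.reported_start_min)
        for job in per_nurse_jobs[nurse.hcw_id]:
            start = int(round(max(cursor, job.nominal_min)))
            if job.kind == "care":
                dur = job.duration or 1
                events.append(ActivityEvent(
                    facility_id=facility.facility_id,
                    hcw_id=nurse.hcw_id,
                    obs_date=obs_date,
                    start_min=start,
                    end_min=start + dur,
                    category=_CARE_CODE,
                    patient_id=job.patient_id,
                    is_new_visit=job.visit_type is VisitType.NEW,
                    is_dm_htn=job.condition is ConditionClass.DM_HTN,
                    is_hiv_comorbid=job.hiv,
                ))
            elif job.kind == "idle":
                # duration drawn at placement time so the session's mean
                # matches the daypart it actually starts in
                daypart = Daypart.MORNING if start < NOON_MIN else Daypart.AFTERNOON
                dur = _gamma_minutes(
                    rng, params.idle_session_mean_min[(arm, daypart)],
                    params.idle_session_cv,
                )
                events.append(ActivityEvent(
                    facility_id=facility.facility_id,
                    hcw_id=nurse.hcw_id,
                    obs_date=obs_date,
                    start_min=start,
                    end_min=start + dur,
                    category=_IDLE_CODE,
                ))
            else:
                dur = _gamma_minutes(rng, params.admin_session_mean_min,
                                     params.idle_session_cv)
                events.append(ActivityEvent(
                    facility_id=facility.facility_id,
                    hcw_id=nurse.hcw_id,
                    obs_date=obs_date,
                    start_min=start,
                    end_min=start + dur,
                    category=_ADMIN_CODE,
                ))
            cursor = float(start + dur)
            if cursor >= MINUTES_PER_DAY:
                raise GenerationError(
                    f"schedule for {nurse.hcw_id} runs past midnight; "
                    "increase shadowed staff or lower the arrival intensity"
                )
    events.sort(key=lambda e: (e.hcw_id, e.start_min))
    return events


# ---------------------------------------------------------------------------
# whole-study generation
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    """In-memory synthetic study: events, staff roster, facility list."""

    events: list[ActivityEvent]
    hcws: list[HCWRecord]
    facilities: list[FacilityRecord]
    params: GeneratorParams

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        return write_tms_csv(self.events, self.hcws, self.facilities, out_dir)


def generate_study(
    params: Optional[GeneratorParams] = None,
    out_dir: Optional[str | Path] = None,
) -> StudyBundle:
    """Generate the full synthetic study: ``n_facilities`` clinics, each
    observed on ``visits_per_facility`` dates (two, matching the study
    design).  With a fixed seed the bundle is byte-identical across
    calls.  When ``out_dir`` is given, the three CSV files are written.
    """
    if params is None:
        params = default_params()
    params.validate()
    root = np.random.SeedSequence(params.seed)

    facilities: list[FacilityRecord] = []
    all_hcws: list[HCWRecord] = []
    all_events: list[ActivityEvent] = []
    for fi in range(params.n_facilities):
        fac_rng = np.random.default_rng(
            np.random.SeedSequence(params.seed, spawn_key=(0, fi)))
        facility = make_facility(fi, params, fac_rng)
        roster = _facility_roster(facility, params, fac_rng)
        facilities.append(facility)
        all_hcws.extend(roster)
        nurses = [h for h in roster if h.cadre in {
            Cadre.GENERAL_NURSE, Cadre.NURSING_SISTER, Cadre.NURSE_ASSISTANT,
        }]
        for di in range(params.visits_per_facility):
            day_seed = np.random.SeedSequence(params.seed, spawn_key=(1, fi, di))
            day_rng_seed = int(day_seed.generate_state(1)[0] % (2**31))
            # rotate which nurses are shadowed across visit days
            k = params.shadowed_nurses_per_day
            offset = (di * k) % max(len(nurses), 1)
            rotation = nurses[offset:] + nurses[:offset]
            obs_date = params.start_date + datetime.timedelta(days=7 * di)
            all_events.extend(generate_facility_day(
                facility, params, day_rng_seed,
                hcws=rotation, obs_date=obs_date,
            ))
    bundle = StudyBundle(all_events, all_hcws, facilities, params)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
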