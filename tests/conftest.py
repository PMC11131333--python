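"""Shared fixtures: hand-built micro event sets and synthetic studies."""

from __future__ import annotations

import dataclasses
import datetime

import pytest

from penscaleup.synthetic_data import default_params, generate_study
from penscaleup.tms_core import (
    ActivityEvent,
    Arm,
    FacilityRecord,
    Region,
    VolumeClass,
    default_vocabulary,
)

DAY = datetime.date(2022, 6, 20)
VOCAB = default_vocabulary()


def care_event(hcw="H1", patient="P1", start=500, end=510, facility="F1",
               day=DAY, new=False, dm=True, hiv=False, code="CONSULTATION"):
    return ActivityEvent(
        facility_id=facility, hcw_id=hcw, obs_date=day,
        start_min=start, end_min=end, category=VOCAB[code],
        patient_id=patient, is_new_visit=new, is_dm_htn=dm, is_hiv_comorbid=hiv,
    )


def idle_event(hcw="H1", start=600, end=630, facility="F1", day=DAY, code="IDLE"):
    return ActivityEvent(
        facility_id=facility, hcw_id=hcw, obs_date=day,
        start_min=start, end_min=end, category=VOCAB[code],
    )


def facility(fid="F1", arm=Arm.SOC):
    return FacilityRecord(
        facility_id=fid, region=Region.HHOHHO, arm=arm,
        volume_class=VolumeClass.LOW, n_staff_present=12,
        observation_window=(480, 960),
    )


@pytest.fixture(scope="session")
def default_bundle():
    """The study-calibrated default synthetic study (28 facilities)."""
    return generate_study(default_params())


@pytest.fixture(scope="session")
def big_bundle():
    """A larger synthetic study for parameter-recovery checks."""
    params = dataclasses.replace(default_params(), n_facilities=200, seed=20220620)
    return generate_study(params)
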