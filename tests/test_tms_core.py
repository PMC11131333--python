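"""Core record types, CSV round-trips, validation and visit grouping."""

from __future__ import annotations

import dataclasses
import datetime
from collections import defaultdict

import pytest
from hypothesis import given, settings, strategies as st

from penscaleup.synthetic_data import default_params, generate_study
from penscaleup.tms_core import (
    ActivityGroup,
    DEFAULT_VOCABULARY,
    ParseError,
    SchemaError,
    VisitConsistencyError,
    VocabularyError,
    group_visits,
    parse_tms_csv,
    validate_events,
    write_tms_csv,
)

from conftest import DAY, care_event, idle_event


class TestVocabulary:
    def test_nineteen_codes_partition_into_three_groups(self):
        assert len(DEFAULT_VOCABULARY) == 19
        groups = defaultdict(list)
        for code, cat in DEFAULT_VOCABULARY.items():
            assert cat.code == code
            groups[cat.group].append(code)
        assert set(groups) == set(ActivityGroup)
        assert sum(len(v) for v in groups.values()) == 19


class TestCsvIO:
    def _write_minimal(self, tmp_path, event_row):
        (tmp_path / "tms_events.csv").write_text(
            "facility_id,hcw_id,date,start,end,activity_code,patient_id,"
            "is_new_visit,is_dm_htn,is_hiv_comorbid\n" + event_row
        )
        (tmp_path / "tms_hcws.csv").write_text(
            "hcw_id,facility_id,cadre,reported_start,reported_end\n"
        )
        (tmp_path / "tms_facilities.csv").write_text(
            "facility_id,region,arm,volume_class,n_staff_present,obs_start,obs_end\n"
        )

    def test_clock_times_convert_to_minutes_since_midnight(self, tmp_path):
        self._write_minimal(
            tmp_path,
            "F1,H1,2022-06-20,08:15,08:24,CONSULTATION,P1,false,true,false\n",
        )
        events, hcws, facilities = parse_tms_csv(tmp_path)
        assert len(events) == 1 and not hcws and not facilities
        assert (events[0].start_min, events[0].end_min) == (495, 504)
        assert events[0].obs_date == datetime.date(2022, 6, 20)

    def test_empty_files_with_valid_headers_parse_to_empty_sequences(self, tmp_path):
        self._write_minimal(tmp_path, "")
        events, hcws, facilities = parse_tms_csv(tmp_path)
        assert events == [] and hcws == [] and facilities == []

    def test_round_trip_is_field_for_field_identical(self, tmp_path):
        params = dataclasses.replace(default_params(), n_facilities=3, seed=11)
        bundle = generate_study(params, out_dir=tmp_path)
        events, hcws, facilities = parse_tms_csv(tmp_path)
        assert events == bundle.events
        assert hcws == bundle.hcws
        assert facilities == bundle.facilities
        # and writing again reproduces the bytes of the canonical dialect
        second = tmp_path / "again"
        write_tms_csv(events, hcws, facilities, second)
        for name in ("tms_events.csv", "tms_hcws.csv", "tms_facilities.csv"):
            assert (second / name).read_bytes() == (tmp_path / name).read_bytes()

    def test_missing_column_names_the_column(self, tmp_path):
        self._write_minimal(tmp_path, "")
        (tmp_path / "tms_events.csv").write_text(
            "facility_id,hcw_id,date,start,end,activity_code\n")
        with pytest.raises(SchemaError, match="patient_id"):
            parse_tms_csv(tmp_path)

    def test_unparseable_time_reports_row_number(self, tmp_path):
        self._write_minimal(
            tmp_path, "F1,H1,2022-06-20,8h15,08:24,CONSULTATION,P1,false,true,false\n")
        with pytest.raises(ParseError) as exc:
            parse_tms_csv(tmp_path)
        assert exc.value.row_errors[0][1] == 2  # first data row

    def test_unknown_activity_code_is_a_vocabulary_error(self, tmp_path):
        self._write_minimal(
            tmp_path, "F1,H1,2022-06-20,08:15,08:24,TELEPORT,P1,false,true,false\n")
        with pytest.raises(VocabularyError, match="TELEPORT"):
            parse_tms_csv(tmp_path)


class TestValidation:
    def test_overlapping_events_for_one_hcw_are_reported(self):
        events = [
            care_event(start=495, end=504, patient="P1"),
            care_event(start=500, end=510, patient="P2"),
        ]
        report = validate_events(events)
        assert [i.kind for i in report.issues] == ["overlap"]

    def test_idle_event_with_patient_attributes_is_a_flag_violation(self):
        bad = idle_event()
        bad.patient_id = "P9"
        report = validate_events([bad])
        assert [i.kind for i in report.issues] == ["flags"]

    def test_care_event_without_patient_attributes_is_a_flag_violation(self):
        bad = care_event()
        bad.is_dm_htn = None
        assert [i.kind for i in validate_events([bad]).issues] == ["flags"]

    def test_reversed_interval_is_a_time_order_violation(self):
        bad = idle_event(start=630, end=600)
        kinds = {i.kind for i in validate_events([bad]).issues}
        assert "time_order" in kinds

    def test_synthetic_default_study_is_invariant_clean(self, default_bundle):
        assert validate_events(default_bundle.events).ok


class TestGroupVisits:
    def test_two_care_events_merge_and_durations_sum(self):
        events = [
            care_event(start=500, end=504, patient="P1"),   # 4 min
            care_event(start=520, end=525, patient="P1"),   # 5 min
        ]
        visits = group_visits(events)
        assert len(visits) == 1
        v = visits[0]
        assert v.duration_min == 9
        assert (v.start_min, v.end_min) == (500, 525)

    def test_same_patient_on_two_dates_yields_two_visits(self):
        other_day = DAY + datetime.timedelta(days=7)
        events = [care_event(patient="P1"), care_event(patient="P1", day=other_day)]
        assert len(group_visits(events)) == 2

    def test_conflicting_flags_name_the_patient(self):
        events = [
            care_event(start=500, end=504, patient="P1", new=True),
            care_event(start=520, end=525, patient="P1", new=False),
        ]
        with pytest.raises(VisitConsistencyError, match="P1"):
            group_visits(events)

    def test_non_care_events_never_form_visits(self):
        assert group_visits([idle_event()]) == []

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(
        st.tuples(
            st.integers(0, 5),      # patient index
            st.integers(0, 1430),   # start
            st.integers(1, 9),      # duration
        ),
        min_size=1, max_size=30,
    ))
    def test_durations_match_brute_force_per_patient_sums(self, spec):
        events = [
            care_event(patient=f"P{p}", start=s, end=s + d, hcw=f"H{i}")
            for i, (p, s, d) in enumerate(spec)
        ]
        visits = group_visits(events)
        expected = defaultdict(int)
        for p, _, d in spec:
            expected[f"P{p}"] += d
        assert {v.patient_id: v.duration_min for v in visits} == dict(expected)
        # conservation: total care minutes unchanged by grouping
        assert sum(v.duration_min for v in visits) == sum(d for _, _, d in spec)

    def test_dm_htn_and_other_visit_counts_follow_the_configured_mix(self):
        # a study configured to the observed sample yields that sample's split
        params = dataclasses.replace(default_params(), n_facilities=60, seed=5)
        bundle = generate_study(params)
        visits = group_visits(bundle.events)
        n = len(visits)
        dm = sum(v.condition_class.value == "DM_HTN" for v in visits)
        share = dm / n
        # binomial sampling error around 353/1171
        p = 353 / 1171
        se = (p * (1 - p) / n) ** 0.5
        assert abs(share - p) < 3 * se
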