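"""TMS summary statistics, ANOVA arm comparison, and visit extrapolation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from penscaleup.model import TimeMotionModel
from penscaleup.tms_analysis import (
    OVERALL,
    UndefinedScaleError,
    UndefinedTestError,
    activity_proportions,
    compare_arms,
    extrapolate_visits,
    idle_stats,
    significance_stars,
    summaries_to_frame,
    time_per_patient_stats,
    workday_stats,
)
from penscaleup.tms_core import (
    Cadre,
    HCWRecord,
    group_visits,
)

from conftest import care_event, facility, idle_event


def _cell(rows, statistic, stratum, arm):
    matches = [r for r in rows if
               (r.statistic, r.stratum, r.arm) == (statistic, stratum, arm)]
    assert len(matches) == 1, (statistic, stratum, arm)
    return matches[0]


class TestWorkdayStats:
    def test_single_hcw_gives_degenerate_interval(self):
        hcws = [HCWRecord("H1", "F1", Cadre.GENERAL_NURSE, 480, 990)]  # 08:00-16:30
        rows = workday_stats(hcws, [facility()])
        cell = _cell(rows, "workday_min", "ALL_STAFF", OVERALL)
        assert (cell.n, cell.mean) == (1, 510.0)
        assert cell.ci_low == cell.ci_high == 510.0

    def test_arm_means_recover_calibration_and_19_minute_gap(self, big_bundle):
        rows = workday_stats(big_bundle.hcws, big_bundle.facilities)
        soc = _cell(rows, "workday_min", "ALL_STAFF", "SOC")
        intv = _cell(rows, "workday_min", "ALL_STAFF", "INTERVENTION")
        for cell, target in ((soc, 497.0), (intv, 516.0)):
            se = (cell.ci_high - cell.mean) / 1.96
            assert abs(cell.mean - target) < 2 * se
        # the configured calibration encodes the 19-minute arm gap
        assert abs((intv.mean - soc.mean) - 19.0) < 3.0

    def test_cadre_strata_are_reported(self, big_bundle):
        rows = workday_stats(big_bundle.hcws, big_bundle.facilities)
        strata = {r.stratum for r in rows}
        assert strata == {"ALL_STAFF", "NURSING_STAFF", "EXPERT_CLIENT", "OTHER_STAFF"}


class TestIdleStats:
    def test_no_idle_events_means_zero_totals(self):
        events = [care_event()]
        rows = idle_stats(events, [facility()])
        cell = _cell(rows, "idle_total_min_per_facility_day", "ALL", OVERALL)
        assert cell.mean == 0.0

    def test_three_session_day_has_mean_twenty(self):
        events = [
            idle_event(start=540, end=550),    # 10 min
            idle_event(start=600, end=620),    # 20 min
            idle_event(start=800, end=830),    # 30 min
        ]
        rows = idle_stats(events, [facility()])
        cell = _cell(rows, "idle_session_min_per_hcw", "ALL", OVERALL)
        assert cell.mean == 20.0
        total = _cell(rows, "idle_total_min_per_facility_day", "ALL", OVERALL)
        assert total.mean == 60.0

    def test_daypart_split_recovers_configured_session_means(self, big_bundle):
        rows = idle_stats(big_bundle.events, big_bundle.facilities)
        targets = {
            ("MORNING", "SOC"): 24.0, ("MORNING", "INTERVENTION"): 23.0,
            ("AFTERNOON", "SOC"): 45.0, ("AFTERNOON", "INTERVENTION"): 40.0,
        }
        for (stratum, arm), target in targets.items():
            cell = _cell(rows, "idle_session_min_per_hcw", stratum, arm)
            se = (cell.ci_high - cell.mean) / 1.96
            assert abs(cell.mean - target) < 3 * se, (stratum, arm)
        # the overall session mean is the daypart mixture, so it falls
        # between the two configured daypart means for each arm
        for arm, (lo, hi) in (("SOC", (24.0, 45.0)), ("INTERVENTION", (23.0, 40.0))):
            cell = _cell(rows, "idle_session_min_per_hcw", "ALL", arm)
            assert lo < cell.mean < hi


class TestTimePerPatient:
    def test_single_visit_degenerate_interval(self):
        visits = group_visits([care_event(start=500, end=509)])
        rows = time_per_patient_stats(visits, [facility()])
        cell = _cell(rows, "time_per_patient_min", "ALL", OVERALL)
        assert (cell.n, cell.mean, cell.ci_low, cell.ci_high) == (1, 9.0, 9.0, 9.0)

    def test_mean_equals_brute_force_average_on_a_fixture(self):
        rng = np.random.default_rng(4)
        events = [
            care_event(patient=f"P{i}", start=480 + 12 * i,
                       end=480 + 12 * i + int(rng.integers(1, 12)),
                       dm=bool(i % 2))
            for i in range(20)
        ]
        visits = group_visits(events)
        rows = time_per_patient_stats(visits, [facility()])
        cell = _cell(rows, "time_per_patient_min", "ALL", OVERALL)
        assert cell.mean == pytest.approx(np.mean([v.duration_min for v in visits]))
        assert cell.n == 20

    def test_all_patient_arm_means_recover_the_calibrated_mixture(self, big_bundle):
        visits = group_visits(big_bundle.events)
        rows = time_per_patient_stats(visits, big_bundle.facilities)
        # configured truths: printed strata mixed at the configured patient mix
        for arm, truth in (("SOC", 9.898), ("INTERVENTION", 8.392)):
            cell = _cell(rows, "time_per_patient_min", "ALL", arm)
            se = (cell.ci_high - cell.mean) / 1.96
            assert cell.n > 3000
            assert abs(cell.mean - truth) < 2.5 * se, arm

    def test_interval_always_brackets_the_mean(self, big_bundle):
        visits = group_visits(big_bundle.events)
        rows = time_per_patient_stats(visits, big_bundle.facilities)
        for r in rows:
            assert r.ci_low <= r.mean <= r.ci_high
            assert r.n >= 1

    def test_interval_width_shrinks_like_root_n(self, big_bundle):
        visits = group_visits(big_bundle.events)
        durs = [float(v.duration_min) for v in visits]
        rng = np.random.default_rng(0)
        widths = []
        for n in (500, 2000):
            sub = rng.choice(durs, size=n, replace=False)
            se = sub.std(ddof=1) / np.sqrt(n)
            widths.append(2 * 1.96 * se)
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.15)


class TestActivityProportions:
    def test_sixty_care_forty_idle_minutes(self):
        events = [care_event(start=480, end=540), idle_event(start=540, end=580)]
        rows = activity_proportions(events, [facility()])
        assert _cell(rows, "proportion_patient_care", "ALL", OVERALL).mean == 0.6
        assert _cell(rows, "proportion_admin_meeting", "ALL", OVERALL).mean == 0.0
        assert _cell(rows, "proportion_idle_break", "ALL", OVERALL).mean == 0.4

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(
        st.tuples(st.sampled_from(["CONSULTATION", "ADMIN", "IDLE"]),
                  st.integers(1, 60)),
        min_size=1, max_size=10,
    ))
    def test_per_hcw_proportions_sum_to_one(self, blocks):
        start, events = 480, []
        for i, (code, dur) in enumerate(blocks):
            if code == "CONSULTATION":
                events.append(care_event(patient=f"P{i}", start=start,
                                         end=start + dur))
            else:
                events.append(idle_event(start=start, end=start + dur, code=code))
            start += dur
        rows = activity_proportions(events, [facility()])
        shares = [r.mean for r in rows if r.arm == OVERALL]
        assert sum(shares) == pytest.approx(1.0)

    def test_synthetic_defaults_put_care_share_near_71_percent(self, big_bundle):
        rows = activity_proportions(big_bundle.events, big_bundle.facilities)
        care = _cell(rows, "proportion_patient_care", "ALL", OVERALL)
        assert abs(care.mean - 0.71) < 0.05


class TestCompareArms:
    def test_identical_groups_give_f_zero_p_one(self):
        res = compare_arms([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.f_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_two_group_f_equals_pooled_t_squared(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(10, 2, 14), rng.normal(12, 2, 17)
        res = compare_arms(list(a) + list(b), ["a"] * 14 + ["b"] * 17)
        t, p = stats.ttest_ind(a, b, equal_var=True)
        assert res.f_statistic == pytest.approx(t**2)
        assert res.p_value == pytest.approx(p)

    def test_anova_p_agrees_with_permutation_within_one_percent(self):
        rng = np.random.default_rng(15)
        a, b = rng.normal(10, 3, 12), rng.normal(12, 3, 12)
        values = np.concatenate([a, b])
        res = compare_arms(values, ["a"] * 12 + ["b"] * 12)
        # permutation distribution of the F statistic
        n_perm, count = 10_000, 0
        prng = np.random.default_rng(0)
        for _ in range(n_perm):
            perm = prng.permutation(values)
            f, _ = stats.f_oneway(perm[:12], perm[12:])
            count += f >= res.f_statistic
        assert abs(res.p_value - count / n_perm) < 0.01

    def test_workday_difference_is_significant_on_synthetic_defaults(
            self, default_bundle):
        arm_of = {f.facility_id: f.arm.value for f in default_bundle.facilities}
        values = [float(h.reported_workday_min) for h in default_bundle.hcws]
        labels = [arm_of[h.facility_id] for h in default_bundle.hcws]
        res = compare_arms(values, labels, "workday_min")
        assert res.p_value < 0.001
        assert significance_stars(res.p_value) == "***"

    def test_single_group_or_singleton_group_is_undefined(self):
        with pytest.raises(UndefinedTestError):
            compare_arms([1, 2, 3], ["a", "a", "a"])
        with pytest.raises(UndefinedTestError):
            compare_arms([1, 2, 3], ["a", "a", "b"])


class TestExtrapolation:
    def _frame(self, obs, start, end):
        return pd.DataFrame([{
            "facility_id": "F1", "arm": "SOC",
            "obs_start_min": start, "obs_end_min": end,
            "observed_visits": obs,
        }])

    def test_full_coverage_is_the_identity(self):
        out = extrapolate_visits(self._frame(21, 480, 960), (480, 960))
        assert out["estimated_visits"].iloc[0] == pytest.approx(21.0)
        assert out["estimated_visits_rounded"].iloc[0] == 21

    def test_morning_only_window_scales_by_intensity_ratio(self):
        # 13 observed in 08:00-12:00; opening 08:00-16:00 at intensities 13/4
        out = extrapolate_visits(self._frame(13, 480, 720), (480, 960), 13.0, 4.0)
        assert out["estimated_visits"].iloc[0] == pytest.approx(17.0)
        assert out["estimated_visits_rounded"].iloc[0] == 17

    def test_extrapolation_is_monotone_in_the_observed_count(self):
        lo = extrapolate_visits(self._frame(5, 480, 720), (480, 960))
        hi = extrapolate_visits(self._frame(9, 480, 720), (480, 960))
        assert hi["estimated_visits"].iloc[0] > lo["estimated_visits"].iloc[0]

    def test_zero_expected_arrivals_in_window_is_an_error(self):
        frame = self._frame(3, 720, 960)
        with pytest.raises(UndefinedScaleError):
            extrapolate_visits(frame, (480, 960), 13.0, 0.0)

    def test_study_totals_match_poisson_expectation(self, big_bundle):
        visits = group_visits(big_bundle.events)
        counts = {}
        for v in visits:
            counts[(v.facility_id, v.obs_date)] = \
                counts.get((v.facility_id, v.obs_date), 0) + 1
        arm_of = {f.facility_id: f.arm.value for f in big_bundle.facilities}
        frame = pd.DataFrame([
            {"facility_id": fid, "arm": arm_of[fid], "obs_start_min": 480,
             "obs_end_min": 960, "observed_visits": c}
            for (fid, _), c in counts.items()
        ])
        out = extrapolate_visits(frame, (480, 960))
        total = out["estimated_visits"].sum()
        expect = 17.0 * len(counts)
        assert abs(total - expect) < 4 * np.sqrt(expect)


class TestModelFacade:
    def test_fit_produces_tables_and_a_summary(self, default_bundle):
        fit = TimeMotionModel(default_bundle.events, default_bundle.hcws,
                              default_bundle.facilities).fit()
        tables = fit.tables()
        assert set(tables) >= {"workday", "idle", "time_per_patient",
                               "activity_shares", "comparisons"}
        text = fit.summary()
        assert "Time per patient" in text and "ANOVA" in text
        frame = summaries_to_frame(fit.time_per_patient)
        assert (frame["ci_low"] <= frame["mean"]).all()
        assert (frame["mean"] <= frame["ci_high"]).all()
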