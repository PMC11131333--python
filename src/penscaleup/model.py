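"""Model/Results interface over the two analyses in this package.

Follows the fit/results convention of statistical modelling libraries:
a model object is constructed from data (or a scenario), ``fit()``
performs the computation and returns a results object carrying the
estimates, their uncertainty and a ``summary()`` table.

* :class:`TimeMotionModel` — built from TMS observation records;
  fitting produces the workday, idle-time, time-per-patient and
  activity-share summaries with 95% intervals and the arm-comparison
  ANOVA for the headline statistics.
* :class:`ScaleUpModel` — built from a :class:`ScaleUpScenario`;
  fitting evaluates the demand → workforce → costing chain, optionally
  with Monte Carlo parameter uncertainty, and exposes the published
  table shapes (population/demand and cost breakdowns).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .scaleup import ScaleUpScenario, run_scaleup
from .tms_analysis import (
    ArmSummary,
    ComparisonResult,
    activity_proportions,
    compare_arms,
    idle_stats,
    significance_stars,
    summaries_to_frame,
    time_per_patient_stats,
    workday_stats,
)
from .tms_core import (
    ActivityEvent,
    FacilityRecord,
    HCWRecord,
    PatientVisit,
    group_visits,
    parse_tms_csv,
    validate_events,
)
from .uncertainty import MCResult, ParamDistribution, run_monte_carlo

__all__ = [
    "TimeMotionModel",
    "TimeMotionResults",
    "ScaleUpModel",
    "ScaleUpResults",
]


# ---------------------------------------------------------------------------
# time-and-motion
# ---------------------------------------------------------------------------

@dataclass
class TimeMotionResults:
    """Fitted TMS summaries; ``tables()`` returns them as DataFrames."""

    workday: list[ArmSummary]
    idle: list[ArmSummary]
    time_per_patient: list[ArmSummary]
    activity_shares: list[ArmSummary]
    comparisons: list[ComparisonResult]
    visits: list[PatientVisit]
    n_hcws: int
    n_facility_days: int

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "workday": summaries_to_frame(self.workday),
            "idle": summaries_to_frame(self.idle),
            "time_per_patient": summaries_to_frame(self.time_per_patient),
            "activity_shares": summaries_to_frame(self.activity_shares),
            "comparisons": pd.DataFrame({
                "statistic": [c.statistic for c in self.comparisons],
                "f_statistic": [c.f_statistic for c in self.comparisons],
                "p_value": [c.p_value for c in self.comparisons],
                "df_between": [c.df_between for c in self.comparisons],
                "df_within": [c.df_within for c in self.comparisons],
            }),
        }

    def summary(self) -> str:
        lines = [
            "Time-and-motion summary",
            "=" * 60,
            f"HCWs observed: {self.n_hcws}; facility-days: {self.n_facility_days}; "
            f"patient visits: {len(self.visits)}",
            "",
        ]
        for title, rows in (
            ("Reported workday (minutes)", self.workday),
            ("Idle time (minutes)", self.idle),
            ("Time per patient (minutes)", self.time_per_patient),
            ("Share of observed time", self.activity_shares),
        ):
            lines.append(title)
            lines.append("-" * len(title))
            for r in rows:
                lines.append(
                    f"  {r.statistic:32s} {r.stratum:18s} {r.arm:12s} "
                    f"n={r.n:5d}  {r.mean:8.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})"
                )
            lines.append("")
        if self.comparisons:
            lines.append("Arm comparisons (one-way ANOVA)")
            lines.append("-" * 31)
            for c in self.comparisons:
                lines.append(
                    f"  {c.statistic:32s} F({c.df_between},{c.df_within}) = "
                    f"{c.f_statistic:.2f}, p = {c.p_value:.4g} "
                    f"{significance_stars(c.p_value)}"
                )
        return "\n".join(lines)


class TimeMotionModel:
    """Time-and-motion analysis of a validated TMS record bundle."""

    def __init__(
        self,
        events: Sequence[ActivityEvent],
        hcws: Sequence[HCWRecord],
        facilities: Sequence[FacilityRecord],
        validate: bool = True,
    ):
        if validate:
            report = validate_events(events)
            if not report.ok:
                raise ValueError(
                    f"events violate {len(report)} invariant(s); "
                    "inspect validate_events() output"
                )
        self.events = list(events)
        self.hcws = list(hcws)
        self.facilities = list(facilities)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "TimeMotionModel":
        events, hcws, facilities = parse_tms_csv(path)
        return cls(events, hcws, facilities, **kwargs)

    def fit(self) -> TimeMotionResults:
        visits = group_visits(self.events)
        arm_of = {f.facility_id: f.arm.value for f in self.facilities}

        comparisons: list[ComparisonResult] = []
        # workday by arm across HCWs
        wd_vals = [float(h.reported_workday_min) for h in self.hcws
                   if h.facility_id in arm_of]
        wd_labs = [arm_of[h.facility_id] for h in self.hcws
                   if h.facility_id in arm_of]
        if len(set(wd_labs)) == 2 and all(wd_labs.count(a) >= 2 for a in set(wd_labs)):
            comparisons.append(compare_arms(wd_vals, wd_labs, "workday_min"))
        # time per patient by arm across visits
        tp_vals = [float(v.duration_min) for v in visits if v.facility_id in arm_of]
        tp_labs = [arm_of[v.facility_id] for v in visits if v.facility_id in arm_of]
        if len(set(tp_labs)) == 2 and all(tp_labs.count(a) >= 2 for a in set(tp_labs)):
            comparisons.append(compare_arms(tp_vals, tp_labs, "time_per_patient_min"))

        return TimeMotionResults(
            workday=workday_stats(self.hcws, self.facilities),
            idle=idle_stats(self.events, self.facilities),
            time_per_patient=time_per_patient_stats(visits, self.facilities),
            activity_shares=activity_proportions(self.events, self.facilities),
            comparisons=comparisons,
            visits=visits,
            n_hcws=len({e.hcw_id for e in self.events}),
            n_facility_days=len({(e.facility_id, e.obs_date) for e in self.events}),
        )


# ---------------------------------------------------------------------------
# scale-up
# ---------------------------------------------------------------------------

def _millions(x: float) -> str:
    return f"{x / 1e6:.2f}"


@dataclass
class ScaleUpResults:
    """Point estimates (and, when fitted with draws, Monte Carlo
    percentile intervals) for every scale-up output."""

    point: dict[str, float]
    mc: Optional[dict[str, MCResult]] = None
    scenario: ScaleUpScenario = field(default_factory=ScaleUpScenario)

    def _interval(self, key: str) -> str:
        if self.mc is None or key not in self.mc:
            return ""
        r = self.mc[key]
        return f" ({r.ci_low:,.0f}-{r.ci_high:,.0f})"

    def demand_table(self) -> pd.DataFrame:
        p = self.point
        rows = [
            ("total_patients", p["total_patients"]),
            ("annual_visits", p["annual_visits"]),
            ("fold_increase_vs_2022", p["fold_increase"]),
            ("realized_visit_share", p["realized_visit_share"]),
            ("care_seeking_share", p["care_seeking_share"]),
        ]
        df = pd.DataFrame(rows, columns=["quantity", "value"])
        if self.mc is not None:
            df["ci_low"] = [self.mc[k].ci_low if k in self.mc else float("nan")
                            for k, _ in rows]
            df["ci_high"] = [self.mc[k].ci_high if k in self.mc else float("nan")
                             for k, _ in rows]
        return df

    def cost_table(self) -> pd.DataFrame:
        p = self.point
        rows = []
        for prefix, arm in (("soc", "SOC"), ("int", "INTERVENTION")):
            for comp in ("personnel_total", "personnel_salary", "personnel_training",
                         "medication_total", "diagnostics_total", "total_cost"):
                key = f"{prefix}_{comp}"
                row = {"arm": arm, "component": comp, "usd": p[key]}
                if self.mc is not None and key in self.mc:
                    row["ci_low"] = self.mc[key].ci_low
                    row["ci_high"] = self.mc[key].ci_high
                rows.append(row)
        return pd.DataFrame(rows)

    def workforce_table(self) -> pd.DataFrame:
        p = self.point
        return pd.DataFrame([
            {"arm": "SOC", "annual_capacity_visits_per_nurse": p["soc_capacity"],
             "nurses_required": int(p["soc_nurses"]),
             "cost_per_visit_usd": p["soc_cost_per_visit"]},
            {"arm": "INTERVENTION",
             "annual_capacity_visits_per_nurse": p["int_capacity"],
             "nurses_required": int(p["int_nurses"]),
             "cost_per_visit_usd": p["int_cost_per_visit"]},
        ])

    def summary(self) -> str:
        p = self.point
        lines = [
            "National DM/HTN scale-up summary",
            "=" * 60,
            "Demand",
            "------",
            f"  Total estimated DM/HTN patients : {p['total_patients']:,.0f}"
            + self._interval("total_patients"),
            f"  Projected annual visits         : {p['annual_visits']:,.0f}"
            + self._interval("annual_visits"),
            f"  Fold increase vs 2022 volume    : {p['fold_increase']:.1f}x",
            f"  Realized share of potential     : {p['realized_visit_share']:.0%}",
            f"  Care-seeking share (2022)       : {p['care_seeking_share']:.1%}",
            "",
            "Workforce",
            "---------",
            f"  Nurses required, standard of care: {p['soc_nurses']:,.0f} "
            f"(capacity {p['soc_capacity']:,.0f} visits/nurse/year)",
            f"  Nurses required, intervention    : {p['int_nurses']:,.0f} "
            f"(capacity {p['int_capacity']:,.0f} visits/nurse/year)",
            "",
            "Annual cost (million USD)",
            "-------------------------",
            "  component           SOC     intervention",
            f"  personnel        {_millions(p['soc_personnel_total']):>7} "
            f"{_millions(p['int_personnel_total']):>12}",
            f"  medication       {_millions(p['soc_medication_total']):>7} "
            f"{_millions(p['int_medication_total']):>12}",
            f"  diagnostics      {_millions(p['soc_diagnostics_total']):>7} "
            f"{_millions(p['int_diagnostics_total']):>12}",
            f"  total            {_millions(p['soc_total_cost']):>7} "
            f"{_millions(p['int_total_cost']):>12}",
            "",
            f"  Cost per visit: ${p['soc_cost_per_visit']:.2f} (SOC), "
            f"${p['int_cost_per_visit']:.2f} (intervention)",
            f"  Standard of care costs {p['soc_premium_fraction']:.0%} more "
            "than the intervention scale-up.",
        ]
        return "\n".join(lines)


class ScaleUpModel:
    """The national scale-up computation as a fittable model."""

    def __init__(self, scenario: Optional[ScaleUpScenario] = None):
        self.scenario = scenario if scenario is not None else ScaleUpScenario()

    @classmethod
    def from_config(cls, path: str | Path) -> "ScaleUpModel":
        from .cli_report import load_scenario_config
        return cls(load_scenario_config(path).build_scenario())

    def fit(
        self,
        n_draws: int = 0,
        seed: int = 0,
        distributions: Optional[Sequence[ParamDistribution]] = None,
    ) -> ScaleUpResults:
        """Evaluate the pipeline; with ``n_draws`` > 0 also run the
        Monte Carlo uncertainty analysis."""
        point = run_scaleup(self.scenario)
        mc = None
        if n_draws > 0:
            mc = run_monte_carlo(self.scenario, distributions=distributions,
                                 n_draws=n_draws, seed=seed)
        return ScaleUpResults(point=point, mc=mc, scenario=self.scenario)
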