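"""Probabilistic uncertainty analysis for the scale-up pipeline.

Parameter uncertainty is propagated by Monte Carlo: each draw samples
every parameter that has a distribution, re-runs the full demand →
workforce → costing chain, and every scalar output is summarised by its
empirical mean and a percentile interval (2.5th/97.5th by default),
alongside the point estimate obtained at central parameter values.

Distribution families: NORMAL for symmetric count estimates (standard
deviation recovered from a printed 95% interval as half-width / 1.96),
GAMMA for positive unit costs and durations, BETA for fractions,
TRIANGULAR for judgement ranges, FIXED for no uncertainty.

Sampling uses common random numbers: each distribution maps a uniform
variate through its quantile function, and distributions sharing a
``shock_group`` share that variate within a draw, making differences
between correlated quantities (for instance the two arms, or patient
counts that move together) less noisy than their levels.  Draws that
violate joint constraints — the comorbid count exceeding either
condition's count, or any negative count — are rejected and resampled,
keeping the marginals interpretable; a rejection rate above 10% raises
an error since it signals misspecified distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from .demand_projection import CIValue, InconsistentInputsError
from .scaleup import ScaleUpScenario, run_scaleup
from .tms_core import Arm

__all__ = [
    "DistFamily",
    "ParamDistribution",
    "MCResult",
    "run_monte_carlo",
    "percentile_ci",
    "default_distributions",
    "MisspecifiedDistributionError",
    "sd_from_ci",
]

Z95 = 1.959963984540054


class MisspecifiedDistributionError(RuntimeError):
    """More than 10% of draws violated joint constraints."""


class DistFamily(str, Enum):
    NORMAL = "NORMAL"
    GAMMA = "GAMMA"
    BETA = "BETA"
    TRIANGULAR = "TRIANGULAR"
    FIXED = "FIXED"


def sd_from_ci(low: float, high: float) -> float:
    """Standard deviation implied by a printed 95% interval (half-width / 1.96)."""
    if high < low:
        raise ValueError("interval bounds out of order")
    return (high - low) / 2.0 / Z95


@dataclass
class ParamDistribution:
    """Marginal distribution of one scenario parameter.

    ``params`` is family-specific: NORMAL {mu, sigma}; GAMMA {mean, cv};
    BETA {alpha, beta}; TRIANGULAR {left, mode, right}; FIXED {value}.
    ``lower``/``upper`` clip the draw to a domain (e.g. counts >= 0).
    Distributions with the same ``shock_group`` share their uniform
    variate within each draw (common random numbers).
    """

    name: str
    family: DistFamily
    params: dict[str, float]
    lower: Optional[float] = None
    upper: Optional[float] = None
    shock_group: Optional[str] = None

    def quantile(self, u: float) -> float:
        p = self.params
        if self.family is DistFamily.FIXED:
            x = p["value"]
        elif self.family is DistFamily.NORMAL:
            x = stats.norm.ppf(u, loc=p["mu"], scale=p["sigma"])
        elif self.family is DistFamily.GAMMA:
            mean, cv = p["mean"], p["cv"]
            if cv <= 0:
                x = mean
            else:
                shape = 1.0 / cv**2
                x = stats.gamma.ppf(u, a=shape, scale=mean / shape)
        elif self.family is DistFamily.BETA:
            x = stats.beta.ppf(u, a=p["alpha"], b=p["beta"])
        elif self.family is DistFamily.TRIANGULAR:
            left, mode, right = p["left"], p["mode"], p["right"]
            width = right - left
            c = (mode - left) / width if width > 0 else 0.5
            x = stats.triang.ppf(u, c=c, loc=left, scale=width)
        else:  # pragma: no cover
            raise ValueError(f"unknown family {self.family}")
        if self.lower is not None:
            x = max(x, self.lower)
        if self.upper is not None:
            x = min(x, self.upper)
        return float(x)


@dataclass
class MCResult:
    """Monte Carlo summary of one scalar output."""

    name: str
    point: float       # model output at central parameter values
    mean: float
    ci_low: float      # 2.5th percentile of draws
    ci_high: float     # 97.5th percentile of draws
    n_draws: int
    seed: int


def percentile_ci(draws: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Empirical percentile interval with linear interpolation between
    order statistics.  ``level`` 0 degenerates to (median, median) by
    convention."""
    arr = np.asarray(list(draws), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two draws")
    if not (0.0 <= level < 1.0):
        raise ValueError("level must lie in [0, 1)")
    if level == 0.0:
        med = float(np.median(arr))
        return med, med
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(arr, [100 * alpha, 100 * (1 - alpha)], method="linear")
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# wiring distributions to scenario fields
# ---------------------------------------------------------------------------

def _set_ci_count(attr: str) -> Callable[[ScaleUpScenario, float], None]:
    def setter(s: ScaleUpScenario, x: float) -> None:
        setattr(s.population, attr, CIValue(x, x, x))
    return setter


def _set_capacity(arm: Arm) -> Callable[[ScaleUpScenario, float], None]:
    def setter(s: ScaleUpScenario, x: float) -> None:
        s.capacity.visits_per_nurse_year[arm] = x
    return setter


def _set_diagnostics(arm: Arm) -> Callable[[ScaleUpScenario, float], None]:
    def setter(s: ScaleUpScenario, x: float) -> None:
        s.costs.diagnostics_usd_year[arm] = x
    return setter


#: Samplable parameter names → how a drawn value enters the scenario.
PARAMETER_SETTERS: dict[str, Callable[[ScaleUpScenario, float], None]] = {
    "dm_patients": _set_ci_count("dm_patients"),
    "htn_patients": _set_ci_count("htn_patients"),
    "comorbid_patients": _set_ci_count("comorbid_patients"),
    "visits_per_patient_year": lambda s, x: setattr(
        s.population, "visits_per_patient_year", x),
    "nurse_salary_usd_year": lambda s, x: setattr(
        s.costs, "nurse_salary_usd_year", x),
    "training_usd_per_nurse": lambda s, x: setattr(
        s.costs, "training_usd_per_nurse", x),
    "med_dm_usd_patient_year": lambda s, x: setattr(
        s.costs, "med_dm_usd_patient_year", x),
    "med_htn_usd_patient_year": lambda s, x: setattr(
        s.costs, "med_htn_usd_patient_year", x),
    "soc_visits_per_nurse_year": _set_capacity(Arm.SOC),
    "int_visits_per_nurse_year": _set_capacity(Arm.INTERVENTION),
    "soc_diagnostics_usd_year": _set_diagnostics(Arm.SOC),
    "int_diagnostics_usd_year": _set_diagnostics(Arm.INTERVENTION),
}


def default_distributions(
    scenario: Optional[ScaleUpScenario] = None,
) -> list[ParamDistribution]:
    """Default sampling plan: the three patient counts, NORMAL with the
    standard deviation implied by their configured 95% intervals.

    The diabetes and comorbid counts share a shock group: the comorbid
    pool is essentially the diabetics who also have hypertension (its
    default interval is the diabetes interval shifted by a constant), so
    its uncertainty moves one-for-one with the diabetes estimate.  This
    correlation keeps every draw consistent (the comorbid count can
    never exceed the diabetes count) and reproduces the published
    total-patient interval, which is far narrower than independent
    sampling of the three counts would give.
    """
    if scenario is None:
        scenario = ScaleUpScenario()
    pop = scenario.population
    dists = []
    for attr, group in (
        ("dm_patients", "dm_shock"),
        ("htn_patients", None),
        ("comorbid_patients", "dm_shock"),
    ):
        ci: CIValue = getattr(pop, attr)
        dists.append(ParamDistribution(
            name=attr,
            family=DistFamily.NORMAL,
            params={"mu": ci.value, "sigma": sd_from_ci(ci.low, ci.high)},
            lower=0.0,
            shock_group=group,
        ))
    return dists


def _sample_scenario(
    base: ScaleUpScenario,
    distributions: Sequence[ParamDistribution],
    rng: np.random.Generator,
) -> ScaleUpScenario:
    groups: dict[str, float] = {}
    scenario = base.copy()
    for dist in distributions:
        if dist.name not in PARAMETER_SETTERS:
            raise KeyError(f"no setter for sampled parameter {dist.name!r}")
        if dist.shock_group is not None:
            u = groups.setdefault(dist.shock_group, float(rng.random()))
        else:
            u = float(rng.random())
        PARAMETER_SETTERS[dist.name](scenario, dist.quantile(u))
    return scenario


def run_monte_carlo(
    scenario: ScaleUpScenario,
    distributions: Optional[Sequence[ParamDistribution]] = None,
    n_draws: int = 10_000,
    seed: int = 0,
    max_rejection_rate: float = 0.10,
) -> dict[str, MCResult]:
    """Propagate parameter uncertainty through the full pipeline.

    Returns one :class:`MCResult` per scalar pipeline output.  The point
    estimate is the pipeline at central values; intervals are empirical
    2.5th–97.5th percentiles over ``n_draws`` accepted draws.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be at least 100")
    if distributions is None:
        distributions = default_distributions(scenario)
    point = run_scaleup(scenario)
    rng = np.random.default_rng(seed)

    samples: dict[str, list[float]] = {k: [] for k in point}
    rejected = 0
    accepted = 0
    while accepted < n_draws:
        drawn = _sample_scenario(scenario, distributions, rng)
        try:
            outputs = run_scaleup(drawn)
        except InconsistentInputsError:
            rejected += 1
            if rejected > max_rejection_rate * n_draws and rejected > 100:
                raise MisspecifiedDistributionError(
                    f"{rejected} rejected draws against {accepted} accepted; "
                    "the parameter distributions violate joint constraints too often"
                )
            continue
        accepted += 1
        for k, v in outputs.items():
            samples[k].append(v)

    results: dict[str, MCResult] = {}
    for name, draws in samples.items():
        arr = np.asarray(draws)
        if np.allclose(arr, arr[0]):
            lo = hi = float(arr[0])
        else:
            lo, hi = percentile_ci(arr, 0.95)
        results[name] = MCResult(
            name=name,
            point=point[name],
            mean=float(np.mean(arr)),
            ci_low=lo,
            ci_high=hi,
            n_draws=n_draws,
            seed=seed,
        )
    return results
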