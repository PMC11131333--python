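# Methods

This note documents the models behind `penscaleup`, the provenance of
its default parameters, what the synthetic generator does and does not
emulate, and the numerical conventions used throughout.

## 1. Records and the time-and-motion summaries

An observation campaign is represented by three record kinds
(`tms_core`): activity events (one per continuously observed HCW
activity interval, at one-minute granularity), HCW records (cadre plus
the self-reported workday), and facility records (region, study arm,
volume class, observation window). The 19-code activity vocabulary
partitions into patient care, administration/meetings and idle
time/breaks; the instrument's exact code list is not public, so the
shipped vocabulary is a documented stand-in with the same structure
(10/4/5 codes) and is configurable.

Care events are grouped into one visit per (patient, facility, date);
a visit's duration is the sum of its events' durations, so total care
minutes are conserved exactly under grouping. A visit or idle session
belongs to the morning iff it starts strictly before 12:00.

All summary cells (`tms_analysis`) are means with normal-approximation
95% intervals, mean ± 1.96·SE (the published tables do not state their
CI construction; a t-based interval differs negligibly at the observed
sample sizes). A single observation yields a degenerate zero-width
interval. Activity-time shares are computed per HCW (each HCW's three
shares sum to 1) and averaged across HCWs within arm, which is why
arm-level shares need not sum to 100%. Arm comparisons use one-way
ANOVA; with two groups the F statistic is exactly the squared
pooled-variance t statistic, and the test suite also cross-checks the
p-value against a permutation distribution. Stars follow the published
thresholds (p < 0.005 / p < 0.001).

**Extrapolation.** Observed visit counts in a window [a, b] scale to
full opening hours by the ratio of expected arrivals, using a
two-piece uniform intensity (an expected 13 arrivals spread over the
morning portion of opening hours and 4 over the afternoon). The
procedure is the identity when the window covers opening hours and is
monotone in the observed count. The original study's exact
extrapolation procedure is in unpublished supplementary material; this
daypart-intensity scaling is this package's own documented choice, and
the study's printed extrapolated totals are deliberately not used as
calibration targets.

## 2. The synthetic observation study

The generator (`synthetic_data`) emulates the observation *protocol*,
not a full clinic microsimulation: per facility-day a small number of
nurses (default 2) are shadowed continuously and only their activity
logs become events. This matters because the study-level figures are
only jointly consistent under that protocol — at 13 + 4 arrivals per
facility-day, full-workday logs for four nurses would put the
patient-care share near 7%, whereas shadowing the working nurses
reproduces the observed ~71% care share and ~8 patients per HCW.

Structure and defaults (each traceable to a published summary unless
marked as a modelling default):

| parameter | default | source/rationale |
|---|---|---|
| facilities / visits each | 28 / 2 | study design |
| arm split, low-volume fraction | 0.5, 20/28 | facility table |
| nurses, staff per facility | 4, 12 (means) | facility table |
| arrivals morning/afternoon | Poisson(13) / Poisson(4) | reported morning peak |
| DM/HTN share of visits | 353/1171 | sample composition |
| new-visit share, DM/HTN | 0.06 | 94% follow-up figure |
| new-visit share, other | 0.20 | modelling default (unpublished) |
| HIV-comorbid share of DM/HTN | 23/353 | sample composition |
| service-time means (min) | per (arm, class, type), see below | time-per-patient table |
| service-time CV | 0.5 | modelling default (dispersion unpublished) |
| idle-session means (min) | 24/45 SOC, 23/40 intervention (am/pm) | idle-time table |
| idle-session probability | 0.45 per daypart per nurse-day | fits total idle ≈ 62 min/facility-day |
| admin session | p = 0.25, mean 15 min | fits meeting share of a few % |
| workday (min) | N(497, 35) SOC, N(516, 35) intervention | workday table (8 h 17 m / 8 h 36 m) |
| opening hours | 08:00–16:00 | convention |

Service times are gamma (positive, right-skewed) with the configured
mean and CV, discretised to whole minutes by stochastic rounding
(floor plus a Bernoulli unit on the fractional part), which preserves
the configured mean exactly; round-to-nearest would bias strata by a
few hundredths of a minute. DM/HTN strata use the published new (16.7
/ 11.0 min) and follow-up (10.2 / 8.7 min) means. For non-DM/HTN
patients only the class means (9.6 / 8.2) and the all-patients
new-visit means (11.0 / 9.6) are published; the non-DM/HTN follow-up
means (9.25 / 7.85) are solved so the class means are exact at the
0.20 new-visit share.

A consequence worth stating: the published stratified means are not
mutually consistent with the published all-patients means in the
intervention arm. Mixing the calibrated strata at the configured
patient mix yields an all-patients mean of ≈9.90 min for standard of
care (matching the published 9.9) but ≈8.39 min for the intervention
arm, where the study prints 8.1. The generator calibrates the strata
(the quantities that feed the capacity model); the all-patients
mixture follows arithmetically and is reported as computed.

Scheduling: arrivals are dispatched to the least-busy shadowed nurse;
a later service is delayed when the nurse is occupied (patients
queue), so events never overlap; idle and admin sessions are inserted
at planned break slots, with the session's mean drawn for the daypart
it actually starts in. Every facility-day draws from an independent
`SeedSequence` substream, so changing the facility count or adding
days never perturbs other facilities' records, and a fixed seed makes
the whole bundle byte-identical.

What the generator does *not* emulate: waiting-room dynamics and
triage order, within-day rostering, day-of-week or seasonal patterns,
facility-level random effects in service speed, the Hawthorne effect,
and inter-observer variation. Recovery tests on this data therefore
demonstrate that the summary pipeline measures what the generator
encodes — not that real clinics satisfy these distributional
assumptions.

## 3. Demand projection

Total patients use inclusion–exclusion over the two conditions
(DM + HTN − comorbid; defaults 14,736 + 122,133 − 13,397 = 123,472 for
adults 40+), and annual demand multiplies by 6.52 visits per patient
per year. Two documented data tensions are surfaced rather than
hidden: (i) the 2022 information-system figures imply 145,764/34,803 ≈
4.19 visits per care-seeking patient, not 6.52 — both figures are kept
in `PopulationInputs` so either rate definition can be configured, and
the orchestration layer logs a warning when the configured rate
conflicts with the recorded figures; (ii) the care-seeking share
computes to 34,803/123,472 = 28.2%; the package always reports the
computed ratio. Counts are exogenous: no prevalence modelling, age
structure or incidence dynamics.

## 4. Workforce capacity

Two modes, because they answer different questions:

* **MECHANISTIC** is the transparent throughput identity — workday
  minutes × patient-care fraction × DM/HTN focus fraction × working
  days (default 230 = 260 weekdays minus leave/holidays) ÷ weighted
  visit minutes (new-share-weighted mix of new and follow-up DM/HTN
  durations). At face-value inputs it yields ≈9,800 visits/nurse-year
  for the intervention arm — an upper bound assuming a nurse does
  DM/HTN care for their entire care time.
* **CALIBRATED** (the default) supplies annual visits per nurse
  directly; the defaults of 821 (SOC) and 1,443 (intervention) are
  back-calculated from the published national headcounts (981 and 558
  nurses for 805,039 visits) and reflect that observed nurses serve
  the full patient mix — roughly 6 DM/HTN visits per nurse-day,
  consistent with the observed ~2 DM/HTN patients per HCW per
  observation session.

Headcounts are ceiling divisions ("at least" semantics): the
workforce is never sized below demand. A consistency check ties the
two published headcounts to the published personnel-cost ratio
(981/558 = 8.05/4.58 = 1.758 to three decimals).

## 5. Costing

All arithmetic is in USD at full precision; SZL amounts convert at
18.867 SZL/USD (June 2023); rounding (millions to two decimals, unit
costs to cents) happens only at report time. Salary ($8,077/nurse-year)
and training ($129/nurse) defaults are back-calculated from the
published per-arm personnel totals divided by headcounts, since the
underlying wage schedule is in unpublished supplementary material;
both are plainly overridable. Medication is linear in patient counts
($7.71 DM, $3.15 HTN per patient-year) with comorbid patients counted
in both condition totals — required to reproduce the published totals
from the published counts, and sensible since they receive both drug
regimens. Diagnostics supports a direct per-arm annual total (defaults
$174,900 SOC / $173,310 intervention) and a component build-up
(annualised sphygmomanometer + glucometer per facility, test strips
per DM-related visit). The grand total is exactly the sum of the three
components in every draw, and the per-visit cost is flagged undefined
(None) at zero visits.

## 6. Uncertainty propagation

Monte Carlo with inverse-transform sampling: each parameter
distribution maps a uniform variate through its quantile function
(families: normal for symmetric count estimates with SD = CI
half-width / 1.96, gamma for positive costs/durations, beta for
fractions, triangular for judgement ranges, fixed otherwise).
Distributions can share a *shock group* — a common uniform within each
draw — giving common random numbers, so differences between correlated
quantities are less noisy than their levels.

The default plan samples the three patient counts. The diabetes and
comorbid counts share a shock: the published comorbid interval is the
diabetes interval shifted by a constant (−1,339), i.e. the comorbid
pool was evidently modelled as moving one-for-one with the diabetes
estimate. This correlation keeps every draw feasible (comorbid never
exceeds diabetes) and reproduces the published total-patient interval;
independent sampling of the three counts would both widen that
interval by ~70% and violate the comorbid ≤ DM constraint in roughly a
fifth of draws. Draws violating joint constraints are
rejection-resampled and counted; a rejection rate above 10% raises an
error, as it signals misspecified inputs rather than bad luck.

Intervals are empirical 2.5th–97.5th percentiles (linear interpolation
between order statistics; level 0 degenerates to the median by
convention); the point estimate is the pipeline at central values.
Identical seeds reproduce identical results. The default cost
intervals propagate patient-count uncertainty only; unit-cost or
capacity uncertainty can be added via the scenario's `uncertainty`
block.

## 7. Orchestration

`run_scenario` executes simulate (optional) → summarize → demand →
workforce → costing → uncertainty sequentially; each stage is a pure
function of (inputs, config, seed), so a fixed seed makes the whole
artifact bundle reproducible. The manifest records the config hash,
seed, package version, per-stage wall time and a SHA-256 checksum of
every output file; on failure the partial outputs are kept under a
FAILED marker. Stages communicate only through their documented file
interfaces.

## 8. Problem sizes used in tests

Stochastic tests run derandomised at fixed seeds. Parameter-recovery
checks use synthetic studies of 200–500 facilities (≈5,000–10,000
visits, about a second to generate); the Monte Carlo interval-recovery
check uses 10,000 draws and the convergence property compares 30,000
against 10,000 draws at a 1% relative bound. Recovery assertions use
two standard errors of the estimate (three for heavily right-skewed
session durations and Poisson count checks).

## 9. Known limitations

* The capacity calibration inherits the published headcounts; it is a
  reproduction device, not an independent staffing model. Mechanistic
  mode exists precisely to make the gap between face-value throughput
  and realised DM/HTN capacity visible.
* Costs are provider-perspective only: no patient costs, no insulin or
  inpatient care, no supply-chain or wastage margins; workforce
  modelling has no attrition, hiring pipeline or non-DM/HTN staffing.
* The generator's independence assumptions (no clustering beyond arm,
  iid service times) make synthetic standard errors smaller than
  design-based errors from 28 clustered facilities would be; arm
  comparisons on synthetic data are correspondingly optimistic.
* Multi-day shifts across midnight and paper-form digitisation are out
  of scope; clock times live within a single day.
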