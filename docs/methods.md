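# Methods

## Scope and design

`telecost` evaluates, from a societal perspective, the replacement of an
in-clinic outpatient follow-up by a video consultation in a two-arm
randomized comparison. It is a cost-minimization analysis: the two modes of
care are taken as clinically equivalent, so only cost (and emission)
differences matter. Health-care payer costs (consultation fees, software
licenses), companion costs, QALYs and the life-cycle footprint of the
digital infrastructure are out of scope.

The analysis has two steps: (1) patient-side costs — travel, time,
production losses — summarised per arm and differenced; (2) environmental
impact of the avoided car travel — five pollutant masses and their monetary
valuation — per patient, for the whole telemedicine arm, and extrapolated
to a year of practice.

## Cost model

All quantities are stored one-way (distance, travel time) and doubled
inside the operations that value a round trip. Unit parameters, all
strictly positive, with defaults:

| parameter | default | meaning |
|---|---|---|
| `cost_per_km` | €0.30/km | empirical standard cost of car travel per km (each km travelled, round trip) |
| `time_value_per_hour` | €16.00/h | value of patients' unpaid work and leisure time |
| `gross_hourly_wage` | €29.48/h | average gross hourly wage (Germany, 2021) |
| `working_hours_per_day` | 6.96 h | average workday across full- and part-time employees |
| `eur_to_usd` | 0.97 | display-only conversion rate |

A work absence is valued as one full average workday,
`gross_hourly_wage × working_hours_per_day`; the arm's production loss is
`n_absent` such workdays, averaged over all employed patients of the arm.
Across employed patients the per-patient loss is a scaled binary variable,
so its SD has the closed form `L·sqrt(n_absent·(1−n_absent/n_employed)/(n_employed−1))`.

**Total composition.** The per-patient total on the unemployed basis is
travel cost + total-time cost; the employed basis adds the mean production
loss per employed patient. Travel-time and waiting-time costs are reported
as components but never added to totals: the valued "total time spent on
the appointment" already contains travelling and waiting, and any other
composition double-counts (and is inconsistent with the component totals it
should reproduce).

**Counterfactuals.** For the telemedicine arm the actual travel and
travel-time costs are identically zero; the model also reports what the
avoided trip would have cost. Counterfactual values never enter totals or
differences.

**Rounding.** All arithmetic is carried at full floating precision.
Published cost tables round each component to cents before summing totals;
the reporting layer reproduces that convention (`rounded=True` on the
totals), the API default does not. The discrepancy is below one cent.

## Emission model

Emission factors (g/pkm: greenhouse gases 152, carbon monoxide 0.94,
volatile hydrocarbons 0.15, nitrogen oxides 0.38, particulates 0.006) are
agency figures already normalized to an average car occupancy of 1.4 — the
occupancy is stored as provenance metadata and never divides anything.
Avoided passenger-kilometers per patient are `2 × one-way distance`.
Records travelling by public transport are excluded from car-emission sums
(no public-transport factors are modelled); the shipped reference fixture
marks all records as car travel, matching how the published per-patient
figure was computed from the full-arm mean distance.

The environmental cost rate per pkm is an independent agency parameter, not
derived internally from carbon price × greenhouse-gas factor (the per-pkm
rate covers damages beyond CO2-equivalents: 0.152 kg/pkm × €195/t ≈
€0.030/pkm ≠ €0.05045/pkm). Two linked presets are bundled — (€195/t,
€0.05045/pkm) discounting future welfare, and (€680/t, €0.12885/pkm)
weighting generations equally. Overriding one element of a pair without the
other logs a warning rather than an error, since users may legitimately
supply their own rates.

**Annual extrapolation.** Annual pkm = patients/week × weeks/year × 2 ×
mean one-way distance, default 8 × 48 = 384 avoided visits (weeks/year = 48
back-derived from that published annual count; configurable). The default
distance is the n-weighted mean of the two arms' distance means,
(26·37.00 + 25·31.58)/51 ≈ 34.343 km. The originally published annual
figures imply an unrounded mean distance of ≈ 34.35 km that cannot be
recovered from the rounded group means; from the printed means this
implementation obtains 4009.08 kg greenhouse gases and €1330.65 per year
(8/week), within 0.1% of the published 4009.88 kg and €1330.91. The gap is
documented rather than tuned away. The 16/week scenario is exactly twice
the 8/week scenario by linearity.

## Trial statistics

* **Mann-Whitney U**, two-sided. Exact enumeration of the null distribution
  when `n1·n2 ≤ 400` and the pooled sample is tie-free; otherwise the
  normal approximation with midrank tie correction and continuity
  correction. The reported statistic is the U of the smaller sample. The
  implementation delegates to scipy; independent brute-force enumeration
  oracles live in the test suite.
* **Fisher exact**, two-sided by the point-probability (minimum-likelihood)
  rule — the convention that reproduces the published P=.34 on the 1/20 vs
  3/19 absence table. A direct-enumeration 2×k variant covers the
  three-level age-band table, for which no exact r×c routine is available
  in the scientific Python stack.
* **Sample size**: smallest integer n per arm such that the two-sided
  two-sample t test at level α with noncentrality d·√(n/2) and 2n−2 degrees
  of freedom reaches the requested power, by iterating n over the
  noncentral-t power function. At d = 1.095, power 0.90, α = 0.05 this
  gives 19 per arm; tests cross-check against statsmodels' power solver and
  a 100 000-replicate Monte-Carlo power simulation. The design inflation
  from 19 to 30 recruited per arm (dropout reserve) is advisory and not
  modelled.

P-values are formatted in the clinical convention (".34", "<.001", capped
display at ".99").

## Synthetic cohort generator

Patient-level data of the motivating trial are not public. The generator
emulates them as the study conditions: 26 patients per arm; per-arm target
means/SDs for treatment duration, one-way distance, one-way travel time,
waiting time and total appointment time equal to the published group
statistics; employment probabilities 20/26 and 19/25; absence probabilities
among the employed 1/20 and 3/19; indication, sex and age-band proportions
as published. The telemedicine arm draws hypothetical distance and travel
time from its own published (counterfactual) targets.

Design choices:

* **Family.** Continuous variables default to lognormal (the published
  medians sit below the means for distance and waiting time, indicating
  right skew), moment-matched on the natural scale; a zero-truncated normal
  is offered as an alternative, matching location/scale before truncation
  (exact truncated-moment matching has no closed form, and the truncation
  bias is documented rather than corrected).
* **Dependence.** Travel time couples to distance through a Gaussian copula
  on the quantile scale (correlation configurable, default 0.7). A
  multiplicative distance × pace construction cannot reach the published
  moments — the telemedicine arm's travel-time CV (0.56) is *below* its
  distance CV (0.87), and a positive independent pace factor can only
  inflate CV — whereas the copula leaves both marginals on target.
* **Calibration.** By default each drawn sample is mapped through a
  log-affine transform `v ↦ exp(a + b·log v)` with `(a, b)` solved (CV
  bisection, then mean scaling) so the *realised* sample mean and SD equal
  the targets exactly. The map is monotone, so ranks — and the copula — are
  preserved, and positivity is automatic. Without calibration the
  heavy-tailed lognormal sample SD has a relative standard error above 5%
  even at n = 2000, i.e. raw draws only converge in distribution;
  calibration makes every generated cohort carry the study's first two
  moments. Set `calibrate_moments=False` for fully random moments.
* **Seeding.** The seed is an explicit, mandatory config field; the CLI
  default (20200901, the trial's start month) is just a documented
  constant.

What the generator does **not** emulate: the published medians/IQRs (a
two-parameter family cannot match four statistics; the discrepancy is
accepted), missing questionnaire items (optional fields support them, the
generator does not produce them), any joint structure beyond the
distance-time pair, and per-patient realism of the original cohort.
Consequently, passing tests demonstrate the correctness and invariances of
the computational pipeline on data with the study's marginal structure —
not properties of the real patients.

## Numerical conventions

* Sample SD (n−1) throughout; the SD of a singleton is defined as 0.
* Median and quartiles use linear interpolation between order statistics
  (numpy default); the published tables' quantile rule is unknown, so IQRs
  are not expected to be bit-reproducible.
* Aggregation sorts values first, making statistics exactly independent of
  record order; missing items are excluded per variable, never per record.
* Cohort CSV: UTF-8, comma separator, "." decimal mark, header required;
  floats are written as shortest round-trip representations, so
  write-then-read is the identity on validated cohorts.
* Report rendering is deterministic (fixed column order, fixed formats,
  sorted JSON keys): identical inputs give byte-identical files.
* Reporting precision: euros to 2 decimals, emission masses to 3 decimals
  (4 for the sub-gram per-patient particulate figure), annual masses to 2.

## Known limitations

* Arm-level costing from aggregates is exact only because every cost is
  linear; any nonlinear extension (e.g. tiered travel reimbursement) must
  go through the patient-level route.
* The absence valuation assumes exactly one full average workday per absent
  patient; partial absences are only explored through the
  full-time/part-time workday scenarios (8.2 h / 3.9 h).
* One telemedicine patient in the motivating trial needed a follow-up
  clinic visit; as that visit was treatment-independent it is excluded, and
  protocol-driven extra visits in other datasets are left to the user's
  preprocessing.
* Emission accounting covers car travel only; public-transport,
  video-infrastructure and life-cycle emissions are out of scope.
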