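# telecost

Societal-perspective cost-minimization and avoided-travel emission analysis
for telemedicine follow-up care.

When an outpatient follow-up visit (orthopedic/trauma surgery after knee or
shoulder treatment, in the motivating German trial) is replaced by a video
consultation, society saves the patient's travel costs, the monetary value
of the time spent travelling, waiting and attending, the production lost
when an employed patient misses work — and the emissions of the car trip
that never happens. `telecost` implements that two-step evaluation as a
reusable, tested pipeline for a two-arm randomized comparison
(telemedicine vs in-clinic), plus the supporting trial statistics and a
deterministic sensitivity engine. It is aimed at health-economics and
health-services researchers evaluating digital-health substitutions of
outpatient visits.

## The model

For a patient with one-way home-to-clinic distance $d$ (km), one-way travel
time $t_v$, waiting time $t_w$ and total appointment time $t_a$ (minutes):

* travel cost $C_T = c_{km}\cdot 2d$ (round trip; default $c_{km}$ = €0.30/km),
* time cost of any duration $m$: $C_t = v\cdot m/60$ (default $v$ = €16.00/h),
  applied to $2t_v$, $t_w$ and $t_a$,
* production loss per work absence: one average workday,
  $L = w\cdot h$ (defaults $w$ = €29.48/h gross, $h$ = 6.96 h/day),
* per-patient total = $C_T + C_t(t_a)\;[+\;\bar L_{\text{employed}}]$ —
  travel-time and waiting-time costs are reported but not added again, since
  the valued total appointment time already contains them.

The telemedicine arm's actual travel and travel-time costs are zero; the
counterfactual costs of the avoided trip are reported alongside. Every cost
is linear in its input, so arm means and SDs follow from the group-level
statistics directly.

Avoided emissions use per-passenger-kilometer car factors (152 g/pkm
greenhouse gases, 0.94 CO, 0.15 volatile hydrocarbons, 0.38 NOx, 0.006
particulates, at average occupancy 1.4), with pkm $=2d$ per avoided visit,
and an environmental damage rate of €0.05045/pkm (carbon price €195/t CO2e)
or €0.12885/pkm (€680/t, equal generational welfare). An annual model
extrapolates 8 (or 16) avoided visits per week over 48 weeks.

Trial statistics: exact two-sided Mann-Whitney U (normal approximation with
tie and continuity correction for large or tied samples), two-sided Fisher
exact tests (point-probability rule, including a 2×k enumeration for the
age-band table), and the a priori per-arm sample size by inverting the
noncentral-t power function of the two-sided two-sample t test.

No patient-level data from the motivating trial are public, so the package
ships the published group-level statistics as an exact fixture
(`reference_aggregates()`) and a synthetic cohort generator
(`generate_cohort`) whose marginals are calibrated to those statistics.

## Worked example

```bash
$ telecost reproduce
Total costs per follow-up appointment (EUR, employed patient): telemedicine 16.11, control 92.63
Saving per video consultation (employed): EUR 76.52
Avoided emissions per patient: 11.248 kg greenhouse gases, environmental cost EUR 3.73
Annual model (8/week): 4009.08 kg greenhouse gases, EUR 1330.65
```

Reading: an in-clinic follow-up costs society €92.63 per employed patient
(€18.95 travel + €41.28 total-time cost + €32.40 mean production loss),
a video consultation €16.11 (€5.85 time cost + €10.26 production loss), a
saving of €76.52 per consultation. Each avoided round trip (74 pkm at the
telemedicine arm's mean distance of 37 km) saves 11.248 kg of greenhouse
gases, worth €3.73 at the €195/t carbon valuation; 384 avoided visits per
year save about 4 tonnes of greenhouse gases and €1330 in environmental
costs.

The same pipeline runs on patient-level data:

```bash
telecost simulate --out cohort.csv --seed 20200901      # synthetic two-arm cohort
telecost analyze  --cohort cohort.csv --out report/     # base-case tables
telecost scenarios --cohort cohort.csv --out report/    # + sensitivity scenarios
```

or from Python:

```python
import telecost as tc

report = tc.run_base_case(tc.reference_aggregates())
results = tc.run_scenarios(report, tc.standard_scenarios())
tc.render_report(report, "report/", scenario_results=results)
```

The standard sensitivity set varies the workday valuation (full-time 8.2 h,
part-time 3.9 h — moving the employed-patient saving between €66.78 and
€80.46), the carbon price (€680/t: €9.53 per patient, €247.91 for the
26-patient arm), and the weekly volume (16/week doubles the annual table).

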