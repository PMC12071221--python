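# cep-planner

Station-level ambulance demand analysis and staffing evaluation for a
**community emergency paramedic (CEP)** programme: a single advanced
paramedic in a small vehicle who handles non-time-critical emergency calls —
the roughly one-in-six dispatches that need neither lights-and-sirens
response nor, in most cases, hospital transport.

The package is built around the 17 major rescue stations of Hamburg's
ambulance rescue system (three operational areas: East, South, West) and
answers the planning questions a city EMS directorate faces before piloting
CEPs:

* **Where is the demand?** Rank-based comparisons of areas and stations
  (Kruskal–Wallis with tie correction, Dunn–Bonferroni post-hoc contrasts,
  Spearman correlations), regression diagnostics with the Durbin–Watson
  statistic, and average-linkage hierarchical clustering of stations by
  annual call volume.
* **When is the demand?** An additive time-series model
  `y(t) = g(t) + s(t) + h(t) + ε(t)` with a piecewise-linear trend `g`,
  Fourier seasonal blocks `s(t) = Σₖ (αₖ cos 2πkt/P + βₖ sin 2πkt/P)` for
  the daily/weekly/monthly/yearly cycles, and 0/1 regressors `h` for school
  breaks, legal holidays and events — fitted by ridge-penalized least
  squares with parametric-bootstrap intervals and validated by
  rolling-origin cross-validation (RMSE).
* **How many staff?** The hourly workload model: a slot's demand is
  `rate × 60 min` against a supply of `CEPs-on-duty × 60 min`, giving
  `workload % = demand/supply × 100`, classified against the 85%
  sustainable-utilisation limit and the 100% capacity ceiling; plus
  staff-hour accounting for a catalogue of staffing strategies
  (per-station 24-h CEPs, second 12-h shifts at high-demand stations,
  pooled neighbourhood groups).
* **What if the data are confidential?** A calibrated synthetic call-event
  generator (per-station Poisson counts with diurnal shape, weekly/yearly
  modulation and break/holiday/event uplifts) reproduces the statistical
  structure of the dispatch data, so the entire pipeline is testable
  without access to the real records.

Packaged fixtures hold the published per-station registry (population,
area, annual operation counts with/without transport), the weekday totals,
one station's full 24-slot hourly profile, and the Hamburg 2019 calendar.

## Worked example

Hourly workload of the busiest station (Wandsbek, 4883 non-time-critical
operations/year) with one round-the-clock CEP, then with a second CEP on a
07:00–19:00 shift:

```python
>>> import cep_planner as cp
>>> prof = cp.load_wandsbek_profile()
>>> table = cp.station_workload_table(prof)
>>> round(table.average_workload, 2), table.n_over85
(55.7, 1)
>>> second = cp.group_workload_table([prof], cp.ShiftPlan.with_second_shift(7, 19))
>>> round(second.average_workload, 2)
37.89
```

One CEP is busy 55.70% of the time on average, but the 10–11 a.m. slot runs
at 88.77% — above the 85% limit a sustainable roster allows — so exactly one
slot is flagged. Adding the 12-h second shift halves the daytime slots and
brings the per-CEP average down to 37.89%.

Strategy comparison from the shell:

```console
$ cep-planner plan --strategy 3b
{
  "strategy": "3b",
  "staff_hours_per_year": 122640,
  "area_coverage_pct": 100.0,
  ...
}
```

Strategy 3b (ten pooled station groups, each with a shared 24-h CEP, plus
second 12-h CEPs for the eight busier groups) covers all 17 stations for
122,640 staff hours per year — against 148,920 for one 24-h CEP at every
station and 166,440 when the four high-demand stations also get a second
shift.

Other entry points: `cep-planner stats`, `cluster`, `generate`, `seasonal`,
`compare`, and `run-all` (full pipeline with a hash manifest; deterministic
under a fixed `--seed`).

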