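# Methods

This note documents the models, conventions and numerical choices behind
`cep_planner`, in the order the pipeline runs them.

## Data model and conventions

**Study year.** All arithmetic assumes a 365-day (non-leap) year. Calendar
weeks follow `week = min(ceil(day_of_year/7), 52)`: weeks 1–51 hold exactly
7 days and week 52 absorbs the final 8, so the annual total divided by 52
is the weekly average (48,035/52 = 923.75 for the packaged registry). ISO
weeks were rejected because they produce 53 partial weeks and break that
identity. Hour slots are half-open clock hours `[h:00, h+1:00)`, 0-based.

**Registry.** One record per station: name, 3-letter code, area
(East/South/West), population, area size, population density, and annual
non-time-critical operation counts split by transport outcome. The density
column stores the published values verbatim rather than recomputing
population/area (the published figures differ from the quotient by up to a
few per-mil). Note that the fixture's per-station "without transportation"
percentage, where quoted, is the ratio *without/with*, not *without/total*;
the fixture stores raw counts only, so either convention can be derived.
Iteration order is alphabetical by station name, which makes every
downstream tie-break and output ordering deterministic.

**Calendar fixture.** The break/holiday/event categories are fixed by the
study design (school breaks incl. ski/Pentecost/summer/autumn/Christmas;
Hamburg legal holidays; major events: the three DOM fairs, Harbour
Birthday, Harley Days, Schlagermove, Christopher Street Day, Advent market
season). The concrete 2019 date ranges in
`fixtures/calendar_hamburg_2019.yaml` are the public Hamburg dates,
reconstructed by the package; flags are independent, so a day may be
simultaneously a break day, holiday and event day.

## Rank statistics (demand_stats)

Implemented from their defining formulas — mid-ranks for ties throughout —
with scipy used only for reference distributions; tests cross-check against
scipy/statsmodels and against brute-force enumeration.

* **Kruskal–Wallis:** tie-corrected `H` (divided by
  `1 − Σ(t³−t)/(N³−N)`), p from the χ² upper tail with g−1 df. The χ²
  reference is an approximation: at n ≤ 8 it tracks the exact permutation
  distribution to within 0.02 in the significance tail (p ≲ 0.1) but can
  deviate by 0.1–0.2 in the middle of the distribution; for tiny-sample
  decisions the exact enumeration in the test suite is the authoritative
  check.
* **Dunn–Bonferroni:** `z = Δ(mean rank)/√(V(1/nᵢ+1/nⱼ))` with the
  tie-corrected variance `V = N(N+1)/12 − Σ(t³−t)/(12(N−1))`; two-sided
  normal p, multiplied by the number of pairwise comparisons m = g(g−1)/2
  (per family, capped at 1). With the three areas this is m = 3, which is
  what turns the raw South–West p ≈ 0.006 into the adjusted 0.018.
* **Spearman:** Pearson correlation of mid-rank vectors, p via
  `t = ρ√((n−2)/(1−ρ²))` with n−2 df. Constant sequences are an error
  (undefined ranks), not a silent NaN.
* **OLS + Durbin–Watson:** least-squares slope/intercept, R², adjusted
  R² = 1−(1−R²)(n−1)/(n−2), two-sided slope t-test. The DW statistic is
  `Σ(eₜ−eₜ₋₁)²/Σeₜ²`; its p-value is obtained by simulating the null
  distribution (1000 seeded Gaussian replicates projected through the same
  design's annihilator matrix) and reporting the lower tail, i.e. evidence
  of *positive* autocorrelation. This replaces the Pan/Imhof exact
  algorithm; for a diagnostic the Monte-Carlo resolution (±0.01 at p≈0.05)
  is sufficient.

Reported values are rounded to the conventions used throughout: p to 3
decimals, correlations and R² to 2.

## Station clustering

Agglomerative average linkage (UPGMA) on Euclidean distances, implemented
directly (O(n³) with recomputed Lance–Williams averages) so the tie rule is
part of the contract: among merge candidates at equal average distance, the
pair whose combined sorted member list is alphabetically first wins. This
makes the dendrogram invariant under input permutations and identical
across platforms; scipy's `linkage` is used in the tests as an independent
oracle for the heights.

The default feature is the **1-D annual non-time-critical count,
unscaled**. This is a reconstruction: it reproduces the documented
five-cluster partition of the 17 stations exactly (isolated low-demand
station; two-station low-demand pair; eight mid-demand stations; two-station
higher-demand pair; four high-demand stations ≥ 4494). A 2-D variant
(count, no-transport/with-transport %) is available behind
`features="total,ratio"` and yields the same five clusters.

**Known discrepancy.** The published account also states that a
four-cluster cut would merge the two-station higher-demand pair into the
eight-station block. Under average linkage this is not what the tree does:
the 5→4 merge joins the isolated low-demand station with the two-station
low-demand pair (average distance ≈ 826 on the count scale, versus ≈ 1281
for the claimed merge), and we verified exhaustively that no feature
construction from the registry columns (raw/standardised/min–max/log/sqrt;
1–3 columns; Euclidean, squared-Euclidean or city-block distances) changes
this while still producing the five-cluster partition — only *single*
linkage does, which contradicts the stated method. The package implements
the stated method faithfully and documents the k = 4 claim as not
reproducible; the corresponding acceptance test is expected to fail and is
left failing deliberately.

## Additive seasonal model

Columns of the design matrix: intercept; scaled time `t/span`; hinge terms
`max(0, t−c)/span` for each changepoint; cos/sin pairs per Fourier block;
0/1 effect regressors. Default changepoint grid: 12 candidates evenly
spaced over the first 80% of the training span. Default Fourier orders:
K = 3 for the daily cycle (P = 24 slots, fitted on hourly data), K = 2
weekly (P = 7), K = 2 monthly (P = 30.5), K = 6 yearly (P = 365.25), fitted
on daily totals; mixed-resolution questions are answered by two separate
fits, one per resolution.

**Estimation.** Ridge-penalized least squares: penalty 1.0 on seasonal and
effect columns, 10.0 on changepoint hinges (stronger shrinkage of slope
changes), intercept unpenalized. This is the MAP estimate of a Bayesian
linear model with Gaussian priors and serves as a deterministic, seedable
stand-in for full posterior sampling; the likelihood is Gaussian on counts,
appropriate at city-scale volumes (hundreds of events/day). Uncertainty
comes from a parametric bootstrap (default 500 replicates): noise is
redrawn from N(0, σ̂²) around the fitted curve and the model refit — a
single matrix product per replicate, so the whole procedure is O(p·n·B).

**Significance.** A component (trend, one Fourier block, one effect) is
flagged significant when any of its coefficients' bootstrap percentile
intervals, Bonferroni-adjusted within the component
(level 0.05/#coefficients), excludes zero. The component report also gives
each block's amplitude — the maximum absolute value of its curve over one
period — with a bootstrap 95% interval. Parameter-recovery tests show
injected sinusoids with SNR ≥ 3 at n = 365 are recovered within 20%
relative amplitude error and that a zero-amplitude monthly block is
correctly not flagged.

**Cross-validation.** Rolling origin: train on all data up to a cutoff,
forecast the next `horizon` points, score by RMSE, slide the cutoff by
`step`. Window count is `floor((n − initial − horizon)/step) + 1`
(e.g. 13 windows for a 365-day series with initial 180, horizon 14,
step 14); chronology is structural — test indices always follow the
cutoff. CV fits skip the bootstrap.

## Synthetic event generator

Counts are Poisson per (station, day, hour slot):
`λ = base × shape_h × weekly(weekday) × yearly(doy) × uplift(flags)`.

* **Poisson, not negative binomial:** no dispersion information is
  available to calibrate overdispersion, and Poisson makes calibration
  closed-form: `base = volume / Σ_d modulation(d)` gives an expected annual
  total exactly equal to the configured volume.
* **Multiplicative composition** keeps intensities non-negative; the
  additive model is fitted to these data regardless, and that deliberate
  generator/model mismatch doubles as a robustness check of the fitting
  stage.
* **Defaults** (chosen once to match the qualitative demand findings):
  diurnal shape = the packaged 24-slot hourly profile of the busiest
  station, normalized (the only complete published profile); weekly cosine
  amplitude 0.03 (weekday totals vary only ±4% around their mean and the
  weekday effect is statistically weak); yearly cosine amplitude 0.10
  peaking mid-July (day 196); uplifts × 1.10 on school-break days, × 1.05
  on legal holidays, × 1.20 on event days (Advent-market weeks run 19–28%
  above the weekly average, and event days stack with the yearly peak).
  Transport outcomes are Bernoulli with each station's published
  with-transport share.
* **Scenario scaling:** area-level multipliers (defaults 1.19 East, 1.22
  South, 1.14 West — the observed pandemic-year increases) scale station
  volumes for a "2021-like" year. Per-station values for that year were
  never published, so the scenario is illustrative, not a reproduction.
* **Seeding:** one master seed; station substreams are
  `default_rng([seed, station_index])`, so output is bit-identical per
  seed and independent of which other stations are generated.

What the generator does **not** emulate: spatial coordinates, within-slot
arrival times, overdispersion/bursting, station-specific diurnal shapes
(all stations share one shape), or demand spillover between stations.
Passing tests on synthetic data therefore demonstrate the pipeline's
correctness and calibration, not forecasting skill on real dispatch data.

## Workload and staffing model

Slot workload = `rate × operation_time / (n_cep × 60) × 100` %, with the
mean operation time fixed at 60 minutes by default (an upper-end value for
a compact urban service area; configurable). Rates are annual slot counts
divided by 365, so a station's average workload with one 24-h CEP equals
`annual_total/8760` — e.g. 4.37% for a 383-operation station and 55.74%
for a 4883-operation one. Slots with demand but zero scheduled CEPs are
marked *uncovered* (infinite workload), not a division error.

Feasibility: "sufficient" means no slot above the 85% sustainable limit;
slots above 100% are counted separately as uncovered demand. Group pooling
sums the member stations' slot rates and divides by the CEPs on duty in the
slot; with one shared CEP the group average is therefore exactly the sum of
the member averages.

The second-shift window is 07:00–19:00 (12 h), matching both the published
shift system (12-h shifts start at 7) and every staff-hour total in the
strategy catalogue (4 × 12 × 365 etc.); an alternative "9.00 to 19.00"
phrasing in the source material conflicts with its own 12-hour accounting
and was not adopted — the window is a parameter. Staff-hours per year are
daily scheduled hours × 365, hence always divisible by 365.

**Tolerances for published percentages.** A handful of published station
averages differ from `annual_total/8760` by 0.01–0.03 percentage points
(consistent with averaging pre-rounded hourly rates); comparisons therefore
allow |Δ| ≤ 0.05 pp where that pattern occurs and assert exact 2-decimal
equality where the quotient reproduces the printed value.

## Problem sizes used in tests and the acceptance script

Fixture-based quantities use the full 17-station registry (pure
arithmetic, instantaneous). Stochastic checks use: one full synthetic year
(≈ 48k events), 20 Monte-Carlo replicates for the diurnal-profile
recovery, 300–400 bootstrap replicates for seasonal intervals, 1000
replicates for the DW null, and exhaustive permutation enumeration at
n = 8 for the rank-test oracles. The complete suite runs in well under a
minute on one CPU.

## Known limitations

* The weekly-series correlation (ρ = 0.67) and its DW p-value from the
  source analysis require the real weekly series, which is not published;
  these are covered only qualitatively on synthetic data.
* The published station-count correlation of 0.90 between totals and
  no-transport counts recomputes to ≈ 0.92 from the published table (the
  exact column pairing/coefficient is ambiguous); the package asserts
  ρ ≥ 0.85 rather than equality.
* The weekday regression's published p = 0.341 versus the recomputed 0.354
  is not asserted (same fit reproduces R² = 0.17 and adjusted R² = 0.01
  exactly).
* The k = 4 clustering claim is not reproducible under the stated method
  (see above).
* Queueing effects, travel times, mid-shift floating of shared CEPs and
  the 26 small rescue stations are out of scope.
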