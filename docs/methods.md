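# Methods

This note documents the models, conventions and numerical choices behind
dendropipe, in pipeline order.

## Timestamps and calendar conventions

All timestamps are naive local standard time on a half-hour grid (no DST at
a site near 19° N). Slots are labelled at the *beginning* of the interval
(00:00 … 23:30), so a calendar day is exactly the 48 slots whose labels
share its date; daily summaries and SRI both use the local
midnight-to-midnight day. Stem readings are sensor-relative displacements
in μm; every downstream quantity is a difference, so the origin never
matters (verified by an origin-independence property test).

## Synthetic weather generator

The generator is a monthly-climatology-driven stochastic simulator, not a
physical model. Twelve mid-month anchors per channel are interpolated
periodically to daily values; defaults encode a North American Monsoon
treeline regime: monthly precipitation totals `[20, 12, 10, 8, 30, 190,
230, 235, 277, 105, 60, 43]` mm (annual 1,220 mm, 85.0% in June–October,
September wettest, April driest), monthly mean air temperatures averaging
6.6 °C (May warmest at 8.4 °C, January coldest at 4.2 °C, sub-freezing
monthly minima December–February), soil temperatures averaging ≈8.6 °C and
staying above 3.5 °C in winter, relative humidity averaging 64% with a
September peak of 84%, and insolation highest in early spring and lowest
under September monsoon cloud.

Component models, each with configurable parameters:

* **Precipitation** — per-half-hour Bernoulli occurrence (monthly
  probability, default 0.10 in the monsoon core, 0.015–0.06 otherwise) ×
  exponential intensity whose mean is set from the monthly total, so
  expected monthly totals are conserved by construction. Summing
  half-hourly values reproduces the annual total exactly (conservation
  test).
* **Air temperature** — seasonal daily mean + AR(1) day-to-day synoptic
  anomaly (σ = 1.5 °C, ρ = 0.6) − cloud cooling (1.2 °C per unit cloud
  anomaly) + a diel cosine (monthly half-range ≈4–5.5 °C, max 14:00) +
  slot noise.
* **Cloud** — a daily index `1 − exp(−precip/8 mm)`, centered within each
  year-month so couplings carry only within-month day-to-day variability.
  Cloudy days are cooler, moister (+14% RH per unit anomaly) and darker
  (−55% insolation per unit anomaly), which is what makes the monsoon
  moisture signal visible across Prec, RH, SolRad and VPD simultaneously.
* **Soil temperature** — a seasonal monthly-mean curve plus 0.7× an
  exponentially smoothed (daily EMA, α = 0.4) air-temperature anomaly and a
  small damped diel cycle (0.5 °C): a smoothed, damped transform of air
  temperature. The defaults keep winter soil means above 3.5 °C; the
  subtlety that observed winter soil monthly means can drop below the air
  mean is not reproduced.
* **Pressure, wind, soil moisture** — station-level mean 644 hPa with a
  semidiurnal tide; wind with an afternoon diel peak and gusts =
  speed × (1.25 + gamma noise); soil moisture as a seasonal curve plus a
  slow wetness memory of the cloud index.

All randomness flows from one root `SeedSequence`; identical configs give
bit-identical output.

## Synthetic stem series

Each tree's trace is

```
reading(t) = baseline + C(day(t)) + A·(s(hour) − 1) + N(0, σ_reading)
```

where `C` is the cumulative true daily increment (stepped at midnight), `s`
the normalized diel shape — a rising half-cosine from the 18:30 minimum to
the 11:30 maximum and a steeper falling half-cosine after it — and `A` the
contraction depth (default 60 μm; no published magnitude exists, so this is
deliberately flagged uncalibrated and only shape-checked: the daily maximum
falls before 14:00 on >80% of clean days). Because the increment steps at
midnight and the diel peak is unique, the pipeline's daily maximum sits on
the constructed peak and, with zero reading noise, pipeline SRI equals the
true increment exactly — the ground-truth fidelity test.

The true increment for day *d* is

```
inc(d) = rate(month) · gate(TS_d) · mult(d) · jitter(d),  floored at 0
```

* `rate`: step function over monthly rates `[2, 2, 4, 16, 28, 18, 11, 9,
  7, 3, 2, 2]` μm/day, chosen so the day-weighted April–September mean is
  14.85 μm (the "about 15 μm" regime), May is the top month and
  April–September is the set of months exceeding 5% of annual growth, while
  some growth occurs in every month.
* `gate`: 1 when the daily mean soil temperature is at or above the onset
  threshold (default 5 °C, the middle of the observed 4–6 °C band), else 0.
* `mult`: 1 + 0.4·z(TSmean) in April–May and 1 + 0.4·z(log1p(daily
  precipitation)) in June–July, with z standardized *within* each
  year-month (so the couplings add no seasonal trend and center to one),
  clipped to [0.05, 3]. These are the signals the statistics are expected
  to recover.
* `jitter`: mean-one lognormal (σ = 0.25) day-to-day biological
  variability.

With the default reading noise (4 μm) and five trees, the site-mean daily
SRI over April–September comes out near 15 μm with an SD near 10 μm
(< 20 μm): the SD is dominated by the seasonal spread of the monthly rates
(≈7 μm), the couplings (≈5 μm in their months) and the jitter (≈4 μm).

Artifacts are injected separately and logged (type, position, magnitude):
site-wide outage windows (Poisson, 2/yr, mean 2 days — shared across trees
because outages hit the logger, not the sensor), isolated missing readings
(p = 0.005) and positive additive spikes (p = 10⁻⁴ per reading, magnitude
250 μm + Exp(250 μm), straddling the 350 μm detection threshold so some
spikes are caught by the spurious rule and some are not). A bark-beetle
decline scenario subtracts a linear shrinkage after an onset date; SRI
floors at zero, so cumulative SRI plateaus.

## Ingest

Delimited text, configurable delimiter and missing token. Rows with
unparseable timestamps or non-numeric values are rejected and counted;
duplicate timestamps keep the first occurrence; the output always spans the
full half-hour grid with explicit missing slots. Range checks use inclusive
bounds and flag (never drop) suspect values; relative humidity outside
[0, 100] is additionally treated as missing at read time. Round-tripping a
generated dataset through write/read is bit-exact for values and
missingness; suspect flags are recomputed deterministically rather than
stored in the file.

## Daily summaries

Totals (precipitation, radiation) sum present slots; extremes and means run
over present slots; a day with fewer than 75% of its 48 slots (configurable)
is marked missing rather than summarized from thin air, and an empty day is
missing, not zero. VPD is computed per half hour from the printed SVP/VP
formulas and averaged — a dedicated guard test confirms the daily mean of
half-hourly VPD is used, not the VPD of daily means. The SVP coefficient
set is implemented exactly as printed, with a domain error at or below
−237.3 °C and for pressures not exceeding SVP. Monthly climatology averages
within-year monthly totals across years for the two total-type variables
and daily values for the rest.

## SRI rules

The spurious test applies to the *signed* day-over-day difference before
the zero floor: only positive exceedances (> 350 μm, strict) are spurious;
a drop of any size floors to zero, which is what lets an infested,
shrinking tree read SRI = 0 rather than "spurious". A day after a gap is
missing (`no_previous_max`), never compared across the gap; the same label
covers a missing current-day maximum. Equivalence with a literal
day-by-day restatement of the rule is tested on random gappy series.

Site-level SRI is the arithmetic mean of per-tree SRI over trees with a
nonmissing value that day (median available); on identical noise-free trees
it equals the single-tree series. Cumulative SRI treats missing days as
zero contribution and reports their count. The growing season is the
longest run of months strictly above the 5% share (ties to the earlier
run, no December–January wrap); growth onset is the first run of ≥5
consecutive days above the soil-temperature threshold, the run length
suppressing single-day excursions. Diel decomposition bounds the phases by
the day's extrema (first maximum, subsequent minimum) rather than fixed
clock times, and its increment component reuses the SRI definition.

## Bootstrap statistics

Resampling draws whole days with replacement, iid within the month,
keeping all variables of a day paired. Months qualify with ≥21 paired
days, evaluated pairwise per variable (a variable below the cutoff shows
`/` while its neighbours are tested). Percentiles are empirical order
statistics with linear interpolation; the median is significant when its
absolute value strictly exceeds half the 2.5th–97.5th spread. Degenerate
resamples (zero variance, or PCR selection failure) are redrawn up to 100
times and counted.

Two properties of this rule deserve emphasis. First, it is measurably
anti-conservative at monthly sample sizes: the calibration test in the
acceptance suite measures a ~9–10% rejection rate under independence at
n = 30 (nominal 5%), consistent with the general undercoverage of
bootstrap percentile spreads for correlations at small n. The rule is kept
exactly as documented rather than recalibrated; coefficients near the
significance boundary should be read accordingly. Second, iid resampling
does not model the serial dependence of daily weather; the bootstrap here
serves robustness of the significance decision, not block structure — a
documented limitation.

PCR standardizes predictors within the month (ddof = 1), eigendecomposes
the correlation matrix, drops low-variance components and back-transforms
to original predictor units (β_j = β_std,j / sd(x_j)). The published
component-selection criterion for this procedure is not reproducible from
available sources, so selection is a swappable interface; the default —
retain eigenvalues ≥ 0.7× the mean — is explicitly labelled a stand-in.
Retaining all components reproduces OLS exactly (tested); duplicated
predictors split their loading equally; constant predictors are dropped
with a warning.

## What the synthetic data does and does not show

Passing tests demonstrate that the pipeline recovers *known* signals under
realistic noise, gaps and spikes: the spring soil-temperature and
early-monsoon precipitation couplings surface with the correct signs in
≥80% of seeded runs, and the cloud linkage reproduces the qualitative
early-monsoon pattern (positive Prec/RH, negative SolRad/VPD). They do not
certify behaviour on real records: the generator has no serial dependence
in precipitation occurrence, no snow, no sensor drift or bark-hydration
effects, its diel amplitude is uncalibrated, and within-month seasonal
trends (e.g. rising spring soil temperature) contribute to the monthly
correlations alongside day-to-day anomalies — so monthly coefficients on
synthetic data are stronger and cleaner than field tables. Problem sizes
in the test and acceptance runs (one simulated year for pipeline checks,
seven years for climatology, five trees, 1,000 resamples, 50 recovery
replicates) were chosen as the smallest sizes at which the sampling
tolerances above are meaningful.

## Degenerate inputs and tie-breaks

Empty days are missing; a zero annual SRI total leaves monthly fractions
undefined and flagged; equal-length growing-season runs resolve to the
earlier; the daily maximum takes the first occurrence on ties; bootstrap
percentile ties follow numpy's linear interpolation; a median exactly equal
to the half-spread is not significant.
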