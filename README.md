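# dendropipe

Tools for turning half-hourly point-dendrometer and weather-station logger
records into daily **Stem Radial Increment (SRI)** series and monthly
bootstrapped growth–climate response tables. The package targets
dendroecologists working with automated dendrometer clusters at
high-elevation, monsoon-dominated sites, where records are short, gappy and
noisy, and where the question is *which* environmental variables drive
week-to-week wood growth within each month of the growing season.

Because such field records are rarely public, the package ships a
first-class synthetic generator that emulates a tropical-treeline North
American Monsoon regime (≈1,220 mm annual precipitation with ~85% falling
June–October, a cool monsoon summer, May the warmest month) and the diel
stem-size cycle of a point dendrometer (nocturnal recharge to a pre-noon
maximum, afternoon contraction). The generator emits the exact logger
format the ingest stage reads, plus a ground-truth channel of true daily
increments that the analysis never sees, so every stage of the pipeline can
be exercised and scored end to end.

## The quantities computed

**SRI.** For each tree, the daily maximum stem size `M_t` (μm,
sensor-relative) is extracted, and

```
SRI_t = M_t − M_{t−1},    SRI_t ← 0 if SRI_t < 0,
SRI_t ← missing if SRI_t > 350 μm (spurious sensor jump)
```

A day whose own or previous maximum is missing has missing SRI. Cumulative
SRI, the per-month percentage of annual growth, the >5% growing-season run,
and the soil-temperature growth-onset date are derived from the daily
series. Dendrometer thermal-expansion errors are computed from published
coefficients (17 μm m⁻¹ °C⁻¹ for a point sensor on a ~0.1 m rod,
11.2 μm m⁻¹ °C⁻¹ for a band on the stem circumference).

**Daily weather.** Half-hourly records collapse to the twelve standard
daily variables (SolRad, Prec, TSmax, TSmin, TAmax, TAmin, RH, SWV, AirPr,
WG, WS, VPD). Vapor pressure deficit is computed per half hour from

```
SVP = 6.11 · exp(17.2693882 · AT / (AT + 237.3))        [hPa]
VP  = RH · SVP · P / (RH · SVP + 100 · (P − SVP))       [hPa]
VPD = SVP − VP
```

and summarized by the daily mean (not computed from daily-mean inputs —
the formulas are nonlinear).

**Growth–climate response.** For every month with ≥21 paired days, 1,000
bootstrap resamples of the daily rows give a distribution of Pearson
correlations (and, optionally, principal-component-regression coefficients)
between site SRI and each variable; the median estimate is significant when
its absolute value exceeds half the 2.5th–97.5th percentile spread. Results
are printed as a month × variable table of signed coefficients, `ns`
(tested, not significant) and `/` (insufficient data).

## Worked example

```python
import dendropipe as dp
from dendropipe.daily import summarize_daily
from dendropipe.growth import daily_max, sri, site_sri, cumulative_sri, \
    monthly_growth_fraction, growing_season
from dendropipe.stats import monthly_responses, response_table

weather = dp.generate_weather(dp.ClimateConfig(seed=1), years=1)
stem_cfg = dp.StemConfig(seed=1)
series, truth = dp.generate_stem_series(stem_cfg, weather)
series = [dp.inject_artifacts(s, stem_cfg) for s in series]

site = site_sri({s.tree_id: sri(daily_max(s))["sri"] for s in series})
sel = site[(site.index.month >= 4) & (site.index.month <= 9)].dropna()
print(f"growing-season mean daily SRI: {sel.mean():.1f} um (sd {sel.std():.1f})")

daily = summarize_daily(weather)
results = monthly_responses(site, daily, n_boot=1000, seed=1)
print(response_table(results).loc["2004-04":"2004-07"].to_string())
```

prints

```
growing-season mean daily SRI: 14.7 um (sd 9.5)
        SolRad  Prec TSmax TSmin TAmax TAmin    RH    SWV  AirPr  WG  WS    VPD
month
2004-04  -0.63    ns  0.93  0.93  0.62  0.67  0.76  -0.51     ns  ns  ns   0.37
2004-05  -0.32    ns  0.93  0.92  0.74  0.78  0.42     ns  -0.36  ns  ns     ns
2004-06  -0.81  0.92    ns    ns    ns    ns  0.66     ns     ns  ns  ns  -0.71
2004-07  -0.90  0.94    ns    ns    ns    ns  0.85     0.44    ns  ns  ns  -0.69
```

The mean daily increment over April–September sits near 15 μm, soil
temperature dominates the spring months and precipitation/humidity (with
negative solar-radiation and VPD coefficients) dominate the early monsoon —
the signals the generator encodes.

The same pipeline runs from the shell:

```
dendropipe run --seed 1 --years 1 --out run_out
dendropipe report run_out
```

which also writes daily CSVs, the monthly climatology, per-tree and site
SRI series, the long-format numeric results and a manifest sufficient to
reproduce the run bit-identically.

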