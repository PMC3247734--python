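"""Synthetic half-hourly weather and point-dendrometer traces.

Emulates the climate regime of a tropical treeline site under the North
American Monsoon (a pronounced June-October wet season carrying ~85% of a
~1,220 mm annual total, cool monsoon summers with the warmest month in May,
damped soil temperatures that stay above 3.5 C in winter) together with the
diel stem-size cycle of a point-dendrometer record: nocturnal/morning
expansion to a pre-noon maximum, afternoon contraction, and a seasonal true
radial increment that peaks in May.

The generator exists so that every downstream stage (ingest -> daily ->
growth -> stats) can be exercised and scored without any field download.
Ground truth (the true daily increment per tree) is emitted on a separate
channel that the analysis pipeline never reads.

All randomness flows from one root seed through `numpy.random.SeedSequence`
substreams (one per tree, one per artifact class), so identical configs give
bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ClimateConfig",
    "StemConfig",
    "StemRadiusSeries",
    "ConfigError",
    "generate_weather",
    "generate_stem_series",
    "inject_artifacts",
    "beetle_decline_scenario",
]

SLOTS_PER_DAY = 48
FREQ = "30min"

_DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


class ConfigError(ValueError):
    """A generator configuration field is out of its documented range."""


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

# Monthly climatology defaults (index 0 = January).  Calibration targets:
# annual precipitation 1,220 mm with ~85% falling June-October, September the
# wettest month (277 mm) and April the driest (8 mm); annual mean air
# temperature 6.6 C with May warmest (8.4 C) and January coldest (4.2 C);
# annual mean soil temperature ~8.7 C, winter monthly means > 3.5 C;
# relative humidity averaging 64% with a September peak; insolation highest
# in spring and lowest under September monsoon cloud.
_PRECIP_MM = np.array([20.0, 12.0, 10.0, 8.0, 30.0, 190.0, 230.0, 235.0, 277.0, 105.0, 60.0, 43.0])
_TAIR_MEAN = np.array([4.2, 5.0, 6.4, 7.7, 8.4, 8.0, 7.4, 7.2, 7.1, 6.8, 6.0, 5.0])
_TAIR_HALF_RANGE = np.array([5.1, 5.2, 5.5, 5.4, 5.35, 4.6, 4.2, 4.2, 4.1, 4.6, 5.0, 5.1])
_TSOIL_MEAN = np.array([6.3, 6.5, 7.7, 9.0, 10.2, 10.4, 10.0, 9.6, 9.4, 9.0, 8.4, 7.0])
_RH_MEAN = np.array([55.0, 50.0, 48.0, 52.0, 58.0, 74.0, 78.0, 82.0, 84.0, 72.0, 58.0, 57.0])
_SOLRAD = np.array([16.0, 18.0, 22.0, 21.0, 20.0, 15.0, 13.0, 12.5, 11.0, 13.0, 14.0, 15.0])
_SOIL_MOISTURE = np.array([19.0, 18.0, 16.0, 15.0, 14.0, 20.0, 23.0, 24.0, 24.0, 23.0, 21.0, 20.0])
# Wet-slot occurrence probability per half hour; intensity means are derived
# from the monthly totals so expected totals are conserved by construction.
_PRECIP_OCCURRENCE = np.array([0.02, 0.02, 0.02, 0.015, 0.03, 0.10, 0.10, 0.10, 0.10, 0.06, 0.04, 0.03])

# Monthly true-increment rate (um/day), step function by month.  Day-weighted
# April-September mean is 14.85 um ("about 15 um"); May is the top month and
# April-September is the run of months each exceeding 5% of annual growth.
_MONTHLY_GROWTH = np.array([2.0, 2.0, 4.0, 16.0, 28.0, 18.0, 11.0, 9.0, 7.0, 3.0, 2.0, 2.0])


def _monthly_to_daily(values: np.ndarray, days: pd.DatetimeIndex) -> np.ndarray:
    """Periodic linear interpolation of 12 mid-month anchors onto dates."""
    anchor = np.cumsum(_DAYS_IN_MONTH) - _DAYS_IN_MONTH / 2.0  # mid-month doy
    x = np.concatenate([[anchor[-1] - 365.0], anchor, [anchor[0] + 365.0]])
    y = np.concatenate([[values[-1]], values, [values[0]]])
    doy = days.dayofyear.to_numpy().astype(float)
    # clamp leap day 366 onto the 365-day climatological cycle
    doy = np.minimum(doy, 365.0)
    return np.interp(doy, x, y)


@dataclass
class ClimateConfig:
    """Monthly climatology and event-model parameters driving the weather
    generator.  All monthly arrays are January-first, length 12."""

    monthly_precip_mm: np.ndarray = field(default_factory=lambda: _PRECIP_MM.copy())
    monthly_tair_mean: np.ndarray = field(default_factory=lambda: _TAIR_MEAN.copy())
    monthly_tair_half_range: np.ndarray = field(default_factory=lambda: _TAIR_HALF_RANGE.copy())
    monthly_tsoil_mean: np.ndarray = field(default_factory=lambda: _TSOIL_MEAN.copy())
    monthly_rh_mean: np.ndarray = field(default_factory=lambda: _RH_MEAN.copy())
    monthly_solrad: np.ndarray = field(default_factory=lambda: _SOLRAD.copy())  # MJ m-2 day-1
    monthly_soil_moisture: np.ndarray = field(default_factory=lambda: _SOIL_MOISTURE.copy())
    precip_occurrence: np.ndarray = field(default_factory=lambda: _PRECIP_OCCURRENCE.copy())
    pressure_mean: float = 644.0            # hPa, ~3,760 m a.s.l.
    wind_mean: float = 10.0                 # km/h
    wind_gust_factor: float = 1.25          # gust = speed * (factor + gamma noise)
    synoptic_sd: float = 1.5                # C, day-to-day AR(1) temperature anomaly
    synoptic_rho: float = 0.6
    tsoil_smoothing_alpha: float = 0.4      # daily EMA of air-temperature anomalies
    tsoil_anomaly_gain: float = 0.7
    tsoil_diel_amp: float = 0.5             # C
    cloud_tair_delta: float = 1.2           # C cooling per unit cloud anomaly
    cloud_rh_delta: float = 14.0            # % RH per unit cloud anomaly
    cloud_solrad_factor: float = 0.55       # fractional insolation loss per unit cloud anomaly
    rh_diel_slope: float = 1.6              # % RH per C of within-day warming
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "monthly_precip_mm", "monthly_tair_mean", "monthly_tair_half_range",
            "monthly_tsoil_mean", "monthly_rh_mean", "monthly_solrad",
            "monthly_soil_moisture", "precip_occurrence",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    def validate(self) -> None:
        if self.monthly_precip_mm.shape != (12,) or np.any(self.monthly_precip_mm < 0):
            raise ConfigError("monthly_precip_mm must be 12 non-negative totals")
        if np.any(self.monthly_rh_mean < 0) or np.any(self.monthly_rh_mean > 100):
            raise ConfigError("monthly_rh_mean must lie in [0, 100]")
        if np.any(self.precip_occurrence < 0) or np.any(self.precip_occurrence > 1):
            raise ConfigError("precip_occurrence must lie in [0, 1]")
        if np.any(self.monthly_solrad < 0):
            raise ConfigError("monthly_solrad must be non-negative")
        if self.pressure_mean <= 0:
            raise ConfigError("pressure_mean must be positive")
        if np.any(self.monthly_tair_half_range < 0):
            raise ConfigError("monthly_tair_half_range must be non-negative")


@dataclass
class StemConfig:
    """Per-tree stem series parameters.

    ``seasonal_growth_curve`` maps day-of-year (1..366) to the true daily
    increment rate in um/day; the default is a step function over the monthly
    rates above.  ``diel_amplitude`` is the depth of the midday-to-evening
    contraction.  The soil-temperature and precipitation couplings make the
    true increment respond linearly to the standardized daily soil-temperature
    anomaly in April-May and to the standardized daily wetness anomaly in
    June-July, which is what the growth-climate statistics downstream are
    expected to recover.  The diel amplitude is uncalibrated (no published
    magnitude); the default is set to produce visually similar traces.
    """

    n_trees: int = 5
    site_id: str = "S1"
    baseline_radius: float = 5000.0         # um, sensor-relative origin
    diel_amplitude: float = 60.0            # um contraction depth
    seasonal_growth_curve: np.ndarray = field(
        default_factory=lambda: np.repeat(_MONTHLY_GROWTH, _DAYS_IN_MONTH)[
            np.minimum(np.arange(366), 364)
        ]
    )
    sri_noise_sd: float = 4.0               # um, per half-hourly reading
    increment_jitter_sigma: float = 0.25    # lognormal day-to-day growth jitter
    soil_temp_onset_threshold: float = 5.0  # C; growth gated off below
    tsoil_coupling: float = 0.4             # Apr-May increment response
    precip_coupling: float = 0.4            # Jun-Jul increment response
    # artifact model
    gap_rate: float = 0.005                 # isolated missing readings
    spike_rate: float = 0.0001              # additive spike per reading
    spike_min: float = 250.0                # um; magnitude = min + Exp(scale)
    spike_scale: float = 250.0
    outage_rate: float = 2.0                # expected site outages per year
    outage_mean_days: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.seasonal_growth_curve = np.asarray(self.seasonal_growth_curve, dtype=float)

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ConfigError("n_trees must be >= 1")
        if self.diel_amplitude < 0:
            raise ConfigError("diel_amplitude must be >= 0")
        if self.seasonal_growth_curve.shape != (366,):
            raise ConfigError("seasonal_growth_curve must have length 366 (day-of-year)")
        if np.any(self.seasonal_growth_curve < 0):
            raise ConfigError("true daily increments must be >= 0")
        for name in ("gap_rate", "spike_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.outage_rate < 0 or self.outage_mean_days < 0:
            raise ConfigError("outage parameters must be >= 0")
        if self.sri_noise_sd < 0:
            raise ConfigError("sri_noise_sd must be >= 0")

    def noise_free(self) -> "StemConfig":
        """Copy with all stochastic stem terms switched off (artifacts too)."""
        return replace(
            self, sri_noise_sd=0.0, increment_jitter_sigma=0.0,
            tsoil_coupling=0.0, precip_coupling=0.0,
            gap_rate=0.0, spike_rate=0.0, outage_rate=0.0,
        )


@dataclass
class StemRadiusSeries:
    """One tree's half-hourly stem-size record (um, sensor-relative).

    ``values`` is NaN where ``flags`` says 'missing'; flags are one of
    'ok' | 'missing' | 'suspect'.  ``artifact_log`` (type, start, end,
    magnitude) is populated by :func:`inject_artifacts` so that downstream
    filters can be scored against the truth.
    """

    tree_id: str
    site_id: str
    values: pd.Series
    flags: pd.Series
    artifact_log: pd.DataFrame | None = None

    def copy(self) -> "StemRadiusSeries":
        log = None if self.artifact_log is None else self.artifact_log.copy()
        return StemRadiusSeries(self.tree_id, self.site_id,
                                self.values.copy(), self.flags.copy(), log)


# --------------------------------------------------------------------------
# weather
# --------------------------------------------------------------------------

def _ar1(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    z = rng.normal(0.0, 1.0, n)
    out = np.empty(n)
    acc = 0.0
    innov = sd * np.sqrt(max(1.0 - rho * rho, 0.0))
    for i in range(n):
        acc = rho * acc + innov * z[i]
        out[i] = acc
    return out


def _center_by_month(x: np.ndarray, ym: np.ndarray) -> np.ndarray:
    """Subtract the realized mean of x within each (year, month) group."""
    s = pd.Series(x)
    return (s - s.groupby(ym).transform("mean")).to_numpy()


def generate_weather(
    config: ClimateConfig,
    years: int = 1,
    start_year: int = 2004,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate ``years`` of half-hourly weather on a continuous grid.

    Returns a DataFrame indexed by interval-beginning timestamps with columns
    precip (mm per interval), tair, tsoil (C), soil_moisture (%), rh (%),
    pressure (hPa), solrad (MJ m-2 per interval), wind_speed, wind_gust
    (km/h).  Deterministic for a fixed config and seed.
    """
    config.validate()
    if years < 1:
        raise ConfigError("years must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    start = pd.Timestamp(f"{start_year}-01-01")
    end = pd.Timestamp(f"{start_year + years}-01-01")
    idx = pd.date_range(start, end, freq=FREQ, inclusive="left")
    days = pd.date_range(start, end, freq="D", inclusive="left")
    n_slots, n_days = len(idx), len(days)
    day_of_slot = np.repeat(np.arange(n_days), SLOTS_PER_DAY)
    hod = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
    slot_month = idx.month.to_numpy()
    day_ym = (days.year * 12 + days.month).to_numpy()

    # --- precipitation: Bernoulli occurrence x exponential intensity -------
    p_occ = config.precip_occurrence[slot_month - 1]
    expected_wet = config.precip_occurrence * _DAYS_IN_MONTH * SLOTS_PER_DAY
    with np.errstate(divide="ignore", invalid="ignore"):
        intensity = np.where(expected_wet > 0,
                             config.monthly_precip_mm / np.maximum(expected_wet, 1e-12),
                             0.0)
    wet = rng.random(n_slots) < p_occ
    precip = np.where(wet, rng.exponential(1.0, n_slots) * intensity[slot_month - 1], 0.0)
    precip[config.monthly_precip_mm[slot_month - 1] == 0] = 0.0

    prec_day = np.bincount(day_of_slot, weights=precip, minlength=n_days)
    cloud = 1.0 - np.exp(-prec_day / 8.0)          # 0 = clear, ->1 very wet
    cloud_anom = _center_by_month(cloud, day_ym)

    # --- air temperature ---------------------------------------------------
    tair_seas = _monthly_to_daily(config.monthly_tair_mean, days)
    half_range = _monthly_to_daily(config.monthly_tair_half_range, days)
    synoptic = _ar1(rng, n_days, config.synoptic_sd, config.synoptic_rho)
    tair_day = tair_seas + synoptic - config.cloud_tair_delta * cloud_anom
    diel = np.cos(2.0 * np.pi * (hod - 14.0) / 24.0)  # max 14:00, min 02:00
    tair = tair_day[day_of_slot] + half_range[day_of_slot] * diel \
        + rng.normal(0.0, 0.3, n_slots)

    # --- soil temperature: seasonal curve + smoothed air anomaly -----------
    tsoil_seas = _monthly_to_daily(config.monthly_tsoil_mean, days)
    anom = tair_day - tair_seas
    sm_anom = np.empty(n_days)
    acc = 0.0
    a = config.tsoil_smoothing_alpha
    for i in range(n_days):
        acc = (1.0 - a) * acc + a * anom[i]
        sm_anom[i] = acc
    tsoil_day = tsoil_seas + config.tsoil_anomaly_gain * sm_anom
    tsoil = tsoil_day[day_of_slot] \
        + config.tsoil_diel_amp * np.cos(2.0 * np.pi * (hod - 17.0) / 24.0) \
        + rng.normal(0.0, 0.05, n_slots)

    # --- relative humidity: wetter and cooler -> moister --------------------
    rh_seas = _monthly_to_daily(config.monthly_rh_mean, days)
    rh = rh_seas[day_of_slot] + config.cloud_rh_delta * cloud_anom[day_of_slot] \
        - config.rh_diel_slope * (tair - tair_day[day_of_slot]) \
        + rng.normal(0.0, 2.0, n_slots)
    rh = np.clip(rh, 3.0, 100.0)

    # --- solar radiation: daylight half-sine scaled by daily total ----------
    sol_seas = _monthly_to_daily(config.monthly_solrad, days)
    sol_day = sol_seas * np.clip(1.0 - config.cloud_solrad_factor * cloud_anom, 0.15, 1.8)
    w = np.sin(np.pi * (hod - 6.0) / 12.0)
    w[(hod < 6.0) | (hod > 18.0)] = 0.0
    w = w / w[:SLOTS_PER_DAY].sum()
    solrad = sol_day[day_of_slot] * w

    # --- pressure, wind, soil moisture --------------------------------------
    pressure = config.pressure_mean \
        + 1.2 * np.cos(2.0 * np.pi * (hod - 10.0) / 12.0) \
        + _ar1(rng, n_days, 1.5, 0.8)[day_of_slot] \
        + rng.normal(0.0, 0.2, n_slots)
    wind_base = config.wind_mean * (1.0 + 0.35 * np.cos(2.0 * np.pi * (hod - 15.0) / 24.0))
    wind_speed = np.maximum(
        wind_base + _ar1(rng, n_days, 1.5, 0.5)[day_of_slot] + rng.normal(0.0, 2.0, n_slots),
        0.0,
    )
    wind_gust = wind_speed * (config.wind_gust_factor + rng.gamma(2.0, 0.15, n_slots))

    sm_seas = _monthly_to_daily(config.monthly_soil_moisture, days)
    wet_mem = np.empty(n_days)
    acc = 0.0
    for i in range(n_days):
        acc = 0.75 * acc + 0.25 * cloud_anom[i]
        wet_mem[i] = acc
    sm_day = np.clip(sm_seas + 10.0 * wet_mem, 3.0, 45.0)
    soil_moisture = np.clip(sm_day[day_of_slot] + rng.normal(0.0, 0.3, n_slots), 0.0, 100.0)

    return pd.DataFrame(
        {
            "precip": precip,
            "tair": tair,
            "tsoil": tsoil,
            "soil_moisture": soil_moisture,
            "rh": rh,
            "pressure": pressure,
            "solrad": solrad,
            "wind_speed": wind_speed,
            "wind_gust": wind_gust,
        },
        index=pd.DatetimeIndex(idx, name="timestamp"),
    )


# --------------------------------------------------------------------------
# stem series
# --------------------------------------------------------------------------

def _diel_shape(hod: np.ndarray) -> np.ndarray:
    """Normalized diel stem cycle in [0, 1]: maximum at 11:30 (pre-noon,
    after the nocturnal recharge), minimum at 18:30 (evening, after the
    afternoon contraction)."""
    h = np.asarray(hod, dtype=float)
    s = np.empty_like(h)
    fall = (h >= 11.5) & (h < 18.5)
    s[fall] = 0.5 * (1.0 + np.cos(np.pi * (h[fall] - 11.5) / 7.0))
    hr = (h - 18.5) % 24.0
    rise = ~fall
    s[rise] = 0.5 * (1.0 - np.cos(np.pi * hr[rise] / 17.0))
    return s


def _standardized_anomaly(x: pd.Series) -> pd.Series:
    """Standardize within each (year, month) so only within-month day-to-day
    variability -- what a monthly correlation sees -- enters the coupling."""
    ym = pd.PeriodIndex(x.index, freq="M")
    mu = x.groupby(ym).transform("mean")
    sd = x.groupby(ym).transform(lambda v: v.std(ddof=0))
    z = (x - mu) / sd
    return z.where(np.isfinite(z), 0.0)


def true_daily_increments(
    stem_cfg: StemConfig, weather: pd.DataFrame, rng: np.random.Generator
) -> pd.Series:
    """True increment (um/day) for one tree: seasonal rate, gated off when
    mean daily soil temperature is below the onset threshold, modulated by
    the spring soil-temperature and early-monsoon wetness couplings, with
    mean-one lognormal day-to-day jitter.  Never negative."""
    day = weather.index.floor("D")
    tsoil_day = weather["tsoil"].groupby(day).mean()
    prec_day = weather["precip"].groupby(day).sum()
    dates = tsoil_day.index
    doy = dates.dayofyear.to_numpy()
    base = stem_cfg.seasonal_growth_curve[doy - 1]
    gate = (tsoil_day.to_numpy() >= stem_cfg.soil_temp_onset_threshold).astype(float)

    mult = np.ones(len(dates))
    month = dates.month.to_numpy()
    spring = np.isin(month, (4, 5))
    if stem_cfg.tsoil_coupling != 0.0 and spring.any():
        z = _standardized_anomaly(tsoil_day[spring]).to_numpy()
        mult[spring] += stem_cfg.tsoil_coupling * z
    monsoon = np.isin(month, (6, 7))
    if stem_cfg.precip_coupling != 0.0 and monsoon.any():
        z = _standardized_anomaly(np.log1p(prec_day[monsoon])).to_numpy()
        mult[monsoon] += stem_cfg.precip_coupling * z
    mult = np.clip(mult, 0.05, 3.0)

    sig = stem_cfg.increment_jitter_sigma
    if sig > 0:
        jitter = np.exp(rng.normal(-0.5 * sig * sig, sig, len(dates)))
    else:
        jitter = 1.0
    inc = np.maximum(base * gate * mult * jitter, 0.0)
    return pd.Series(inc, index=dates, name="true_increment_um")


def generate_stem_series(
    stem_cfg: StemConfig,
    weather: pd.DataFrame,
    seed: int | None = None,
) -> tuple[list[StemRadiusSeries], pd.DataFrame]:
    """Build one clean StemRadiusSeries per tree plus the ground-truth table.

    Each series is baseline + cumulative true increment (stepped at local
    midnight) + diel cycle + iid reading noise, so with zero noise the daily
    maximum falls exactly on the constructed pre-noon peak and the pipeline
    SRI equals the true increment.  Ground truth is returned as a long
    DataFrame (date, tree_id, true_increment_um) and is never consumed by
    the analysis pipeline.
    """
    stem_cfg.validate()
    if len(weather) < SLOTS_PER_DAY:
        raise ConfigError("weather span must cover at least one full day")
    if len(weather) % SLOTS_PER_DAY != 0:
        raise ConfigError("weather must cover whole days on the half-hour grid")
    expected = pd.date_range(weather.index[0], periods=len(weather), freq=FREQ)
    if not weather.index.equals(expected):
        raise ConfigError("weather grid has internal gaps or irregular spacing")

    hod = weather.index.hour.to_numpy() + weather.index.minute.to_numpy() / 60.0
    diel = stem_cfg.diel_amplitude * (_diel_shape(hod) - 1.0)

    root = np.random.SeedSequence(stem_cfg.seed if seed is None else seed)
    streams = root.spawn(stem_cfg.n_trees)
    series: list[StemRadiusSeries] = []
    truth_rows = []
    for t, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        tree_id = f"{stem_cfg.site_id}-T{t + 1:02d}"
        inc = true_daily_increments(stem_cfg, weather, rng)
        cum = inc.cumsum()
        values = (
            stem_cfg.baseline_radius
            + np.repeat(cum.to_numpy(), SLOTS_PER_DAY)
            + diel
        )
        if stem_cfg.sri_noise_sd > 0:
            values = values + rng.normal(0.0, stem_cfg.sri_noise_sd, len(values))
        vs = pd.Series(values, index=weather.index, name="stem_um")
        flags = pd.Series("ok", index=weather.index, name="flag")
        series.append(StemRadiusSeries(tree_id, stem_cfg.site_id, vs, flags))
        truth_rows.append(
            pd.DataFrame({"date": inc.index, "tree_id": tree_id,
                          "true_increment_um": inc.to_numpy()})
        )
    truth = pd.concat(truth_rows, ignore_index=True)
    return series, truth


# --------------------------------------------------------------------------
# artifacts
# --------------------------------------------------------------------------

def inject_artifacts(
    series: StemRadiusSeries, stem_cfg: StemConfig
) -> StemRadiusSeries:
    """Insert outage windows (shared across trees of a site), isolated missing
    readings, and additive spikes; every artifact is logged.  Deterministic
    for a fixed config: the outage stream depends only on the config seed and
    the per-tree stream on (seed, tree_id)."""
    stem_cfg.validate()
    out = series.copy()
    idx = out.values.index
    n = len(idx)
    log = []

    # site-wide outages: same draw for every tree of the site
    rng_site = np.random.default_rng(
        np.random.SeedSequence([stem_cfg.seed, 0xA110]))
    years_span = max(n / (SLOTS_PER_DAY * 365.0), 1e-9)
    n_out = rng_site.poisson(stem_cfg.outage_rate * years_span)
    for _ in range(n_out):
        start = int(rng_site.integers(0, n))
        length = max(int(rng_site.exponential(stem_cfg.outage_mean_days)
                         * SLOTS_PER_DAY), SLOTS_PER_DAY // 2)
        stop = min(start + length, n)
        out.values.iloc[start:stop] = np.nan
        out.flags.iloc[start:stop] = "missing"
        log.append(("outage", idx[start], idx[stop - 1], np.nan))

    rng = np.random.default_rng(
        np.random.SeedSequence([stem_cfg.seed, zlib.crc32(series.tree_id.encode())]))
    gaps = rng.random(n) < stem_cfg.gap_rate
    if gaps.any():
        out.values[gaps] = np.nan
        out.flags[gaps] = "missing"
        for ts in idx[gaps]:
            log.append(("gap", ts, ts, np.nan))
    spikes = (rng.random(n) < stem_cfg.spike_rate) & out.values.notna().to_numpy()
    if spikes.any():
        mags = stem_cfg.spike_min + rng.exponential(stem_cfg.spike_scale, int(spikes.sum()))
        out.values[spikes] = out.values[spikes] + mags
        for ts, m in zip(idx[spikes], mags):
            log.append(("spike", ts, ts, float(m)))

    out.artifact_log = pd.DataFrame(
        log, columns=["type", "start", "end", "magnitude"])
    return out


def beetle_decline_scenario(
    series: StemRadiusSeries, onset_day: pd.Timestamp, rate: float
) -> StemRadiusSeries:
    """Superimpose the monotone stem shrinkage of a bark-beetle-infested tree:
    from ``onset_day`` the stem loses ``rate`` um per day, so downstream SRI
    floors at zero and cumulative SRI plateaus."""
    onset = pd.Timestamp(onset_day)
    idx = series.values.index
    if onset < idx[0] or onset > idx[-1]:
        raise ValueError("onset_day outside the series span")
    if rate < 0:
        raise ValueError("decline rate must be >= 0")
    out = series.copy()
    elapsed_days = np.asarray((idx - onset).total_seconds()) / 86400.0
    decline = rate * np.maximum(elapsed_days, 0.0)
    out.values = (out.values - decline).rename(series.values.name)
    return out
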