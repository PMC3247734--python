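"""SRI rules, growth summaries, diel decomposition and thermal arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dendropipe as dp
from dendropipe.growth import (ThermalSpec, cumulative_sri, daily_max,
                               diel_phases, growing_season,
                               monthly_growth_fraction, onset_day, site_sri,
                               sri, thermal_error)


def _series(values, start="2004-06-01"):
    return pd.Series(values, index=pd.date_range(start, periods=len(values),
                                                 freq="D"), dtype=float)


def brute_force_sri(day_max, threshold=350.0):
    """Literal day-by-day restatement of the SRI definition: subtract the
    previous day's maximum from the current day's; negatives become zero;
    positive differences above the threshold become missing."""
    out = []
    vals = list(day_max)
    for i, cur in enumerate(vals):
        prev = vals[i - 1] if i > 0 else np.nan
        if np.isnan(cur) or np.isnan(prev):
            out.append(np.nan)
        else:
            d = cur - prev
            if d > threshold:
                out.append(np.nan)
            elif d < 0:
                out.append(0.0)
            else:
                out.append(d)
    return out


class TestSriRules:
    def test_toy_maxima(self):
        frame = sri(_series([1000, 1015, 1010, 1400]))
        assert np.isnan(frame["sri"].iloc[0])
        assert frame["sri"].iloc[1] == 15.0
        assert frame["sri"].iloc[2] == 0.0
        assert np.isnan(frame["sri"].iloc[3])
        assert list(frame["basis"]) == ["no_previous_max", "ok", "ok", "spurious"]

    def test_constant_maxima_give_zero(self):
        frame = sri(_series([500.0] * 6))
        assert (frame["sri"].iloc[1:] == 0.0).all()

    def test_difference_of_exactly_350_is_retained(self):
        frame = sri(_series([1000.0, 1350.0, 1700.1]))
        assert frame["sri"].iloc[1] == 350.0
        assert frame["basis"].iloc[2] == "spurious"

    def test_large_negative_drop_floors_to_zero_not_spurious(self):
        frame = sri(_series([2000.0, 1400.0]))
        assert frame["sri"].iloc[1] == 0.0
        assert frame["basis"].iloc[1] == "ok"

    def test_day_after_gap_is_missing(self):
        frame = sri(_series([1000.0, np.nan, 1010.0]))
        assert np.isnan(frame["sri"].iloc[2])
        assert frame["basis"].iloc[2] == "no_previous_max"

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            vals = 1000 + np.cumsum(rng.normal(10, 120, 30))
            vals[rng.random(30) < 0.15] = np.nan
            frame = sri(_series(vals))
            expected = brute_force_sri(vals)
            np.testing.assert_allclose(frame["sri"].to_numpy(), expected,
                                       equal_nan=True)

    @settings(deadline=None, max_examples=50)
    @given(offset=st.floats(-1e6, 1e6, allow_nan=False),
           vals=st.lists(st.floats(0, 5000, allow_nan=False),
                         min_size=2, max_size=15))
    def test_origin_independence(self, offset, vals):
        base = sri(_series(vals))["sri"]
        shifted = sri(_series(np.asarray(vals) + offset))["sri"]
        np.testing.assert_allclose(base, shifted, equal_nan=True, atol=1e-6)


class TestDailyMax:
    def test_single_reading_day(self):
        idx = pd.DatetimeIndex(["2004-06-01 10:00"])
        assert daily_max(pd.Series([1000.0], index=idx)).iloc[0] == 1000.0

    def test_fully_missing_day_is_missing(self):
        idx = pd.date_range("2004-06-01", periods=96, freq="30min")
        v = pd.Series(np.nan, index=idx)
        v.iloc[50] = 7.0
        dm = daily_max(v)
        assert np.isnan(dm.iloc[0]) and dm.iloc[1] == 7.0

    def test_noise_free_day_max_is_constructed_peak(self, weather_year, stem_cfg):
        series, truth = dp.generate_stem_series(stem_cfg.noise_free(),
                                                weather_year)
        s = series[0]
        tt = truth[truth.tree_id == s.tree_id].set_index("date")
        dm = daily_max(s)
        expected = stem_cfg.baseline_radius + tt["true_increment_um"].cumsum()
        np.testing.assert_allclose(dm.to_numpy(), expected.to_numpy())


class TestCumulative:
    def test_missing_contributes_zero_and_is_tallied(self):
        cum, n_missing = cumulative_sri(_series([5, 0, np.nan, 10]))
        assert list(cum) == [5, 5, 5, 15]
        assert n_missing == 1

    def test_all_missing_is_flat_zero(self):
        cum, n_missing = cumulative_sri(_series([np.nan] * 4))
        assert (cum == 0).all() and n_missing == 4

    def test_non_decreasing_and_conserves_monthly_totals(self):
        rng = np.random.default_rng(3)
        s = _series(rng.gamma(1.5, 10, 120), start="2004-01-01")
        cum, _ = cumulative_sri(s)
        assert (cum.diff().dropna() >= 0).all()
        monthly = s.groupby(pd.PeriodIndex(s.index, freq="M")).sum()
        assert cum.iloc[-1] == pytest.approx(monthly.sum(), rel=1e-12)


class TestSiteAggregation:
    def test_identical_trees_equal_single_tree(self):
        a = _series([5.0, 10.0, np.nan])
        agg = site_sri({"t1": a, "t2": a.copy(), "t3": a.copy()})
        np.testing.assert_allclose(agg, a, equal_nan=True)

    def test_mean_skips_missing_trees(self):
        agg = site_sri({"t1": _series([4.0, np.nan]), "t2": _series([8.0, 6.0])})
        assert list(agg) == [6.0, 6.0]


class TestMonthlyFractions:
    def test_all_growth_in_may(self):
        idx = pd.date_range("2004-01-01", "2004-12-31", freq="D")
        s = pd.Series(0.0, index=idx)
        s[idx.month == 5] = 2.0
        fr = monthly_growth_fraction(s, 2004)
        assert fr[5] == pytest.approx(100.0)
        assert fr.drop(5).sum() == pytest.approx(0.0)

    def test_uniform_growth_proportional_to_day_count(self):
        idx = pd.date_range("2003-01-01", "2003-12-31", freq="D")
        fr = monthly_growth_fraction(pd.Series(1.0, index=idx), 2003)
        assert fr[1] == pytest.approx(100 * 31 / 365)
        assert fr[2] == pytest.approx(100 * 28 / 365)
        assert fr.sum() == pytest.approx(100.0)

    def test_zero_annual_total_flagged_undefined(self):
        idx = pd.date_range("2004-01-01", periods=40, freq="D")
        fr = monthly_growth_fraction(pd.Series(0.0, index=idx), 2004)
        assert fr.isna().all() and fr.attrs["undefined"]

    def test_default_generator_peaks_in_may(self, clean_stems):
        series, _ = clean_stems
        site = site_sri({s.tree_id: sri(daily_max(s))["sri"] for s in series})
        fr = monthly_growth_fraction(site, 2004)
        assert fr.idxmax() == 5


class TestGrowingSeason:
    def test_april_through_september(self):
        fr = pd.Series([1, 1, 2, 10, 30, 20, 12, 9, 6, 4, 3, 2],
                       index=range(1, 13), dtype=float)
        assert growing_season(fr) == (4, 9)

    def test_uniform_year_is_all_twelve_months(self):
        fr = pd.Series(100 / 12, index=range(1, 13))
        assert growing_season(fr) == (1, 12)

    def test_tie_goes_to_earlier_run(self):
        fr = pd.Series([9, 9, 0, 0, 9, 9, 0, 0, 0, 0, 0, 0],
                       index=range(1, 13), dtype=float)
        assert growing_season(fr) == (1, 2)

    def test_no_month_above_threshold(self):
        fr = pd.Series(4.0, index=range(1, 13))
        assert growing_season(fr) is None

    def test_threshold_is_strict(self):
        fr = pd.Series([5.0] * 11 + [45.0], index=range(1, 13))
        assert growing_season(fr) == (12, 12)


class TestOnset:
    def test_warm_series_onsets_immediately(self):
        s = _series([10.0] * 30, start="2004-03-01")
        assert onset_day(s) == s.index[0]

    def test_cold_series_never_onsets(self):
        assert onset_day(_series([0.0] * 30)) is None

    def test_step_crossing(self):
        vals = [2.0] * 99 + [8.0] * 30
        s = _series(vals, start="2004-01-01")
        assert onset_day(s) == s.index[99]

    def test_short_excursion_does_not_trigger(self):
        vals = [2.0] * 50 + [8.0] * 3 + [2.0] * 50
        assert onset_day(_series(vals)) is None


class TestDielPhases:
    @staticmethod
    def _day(values):
        idx = pd.date_range("2004-06-02", periods=48, freq="30min")
        return pd.Series(values, index=idx, dtype=float)

    def test_monotone_rising_day(self):
        day = self._day(np.linspace(0, 47, 48))
        c, e, inc = diel_phases(day, previous_day_max=40.0)
        assert c == 0.0 and e == 0.0
        assert inc == pytest.approx(7.0)

    def test_perfect_v_shape(self):
        half = np.linspace(100, 50, 24)
        day = self._day(np.concatenate([half, half[::-1]]))
        c, e, inc = diel_phases(day, previous_day_max=100.0)
        assert c == pytest.approx(50.0)
        assert e == pytest.approx(c)
        assert inc == 0.0

    def test_insufficient_coverage_returns_none(self):
        day = self._day(np.linspace(0, 47, 48))
        day.iloc[15:] = np.nan
        assert diel_phases(day, previous_day_max=0.0) is None

    def test_noise_free_increment_matches_truth(self, weather_year, stem_cfg):
        series, truth = dp.generate_stem_series(stem_cfg.noise_free(),
                                                weather_year)
        s = series[0]
        tt = truth[truth.tree_id == s.tree_id].set_index("date")
        dm = daily_max(s)
        day = pd.Timestamp("2004-05-10")
        readings = s.values[s.values.index.floor("D") == day]
        _, _, inc = diel_phases(readings, dm.loc[day - pd.Timedelta(days=1)])
        assert inc == pytest.approx(tt.loc[day, "true_increment_um"], abs=1e-9)


class TestThermalError:
    def test_point_dendrometer_17um_per_10C(self):
        assert thermal_error(ThermalSpec.point(), 10.0) == pytest.approx(17.0)

    def test_band_on_one_meter_circumference(self):
        assert thermal_error(ThermalSpec.band(1.0), 10.0) == pytest.approx(112.0)

    def test_zero_delta_t(self):
        assert thermal_error(ThermalSpec.band(1.0), 0.0) == 0.0

    def test_sign_follows_temperature_change(self):
        assert thermal_error(ThermalSpec.point(), -10.0) == pytest.approx(-17.0)

    def test_trunk_term_reduces_apparent_error(self):
        spec = ThermalSpec("point", 17.0, 0.1, trunk_cte=-3.0)
        assert thermal_error(spec, 10.0, include_trunk=True) == pytest.approx(
            (17.0 - 3.0) * 0.1 * 10.0)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ThermalSpec("point", -1.0, 0.1)
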