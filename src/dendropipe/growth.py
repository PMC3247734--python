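"""Stem Radial Increment (SRI) and derived growth quantities.

Daily SRI is the irreversible part of the diel stem cycle: the maximum stem
size of the current calendar day minus the maximum of the previous day,
with negative differences set to zero (a shrinking stem is not un-growing,
it is dehydrating or, in the beetle-decline scenario, dying) and positive
differences above a spurious threshold (default 350 um) set to missing.
The spurious test is applied to the signed difference *before* the zero
floor, and only positive exceedances are spurious: a large drop of any size
floors to zero, consistent with the shrinkage of infested trees.

SRI is origin-independent (stem readings are sensor-relative displacements)
and a day following a gap is missing rather than compared across the gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import SLOTS_PER_DAY, StemRadiusSeries

__all__ = [
    "SPURIOUS_THRESHOLD_UM",
    "daily_max",
    "sri",
    "site_sri",
    "cumulative_sri",
    "monthly_growth_fraction",
    "growing_season",
    "onset_day",
    "diel_phases",
    "ThermalSpec",
    "thermal_error",
]

SPURIOUS_THRESHOLD_UM = 350.0


def daily_max(series: StemRadiusSeries | pd.Series) -> pd.Series:
    """Maximum stem size per calendar day; missing when every reading of the
    day is missing."""
    values = series.values if isinstance(series, StemRadiusSeries) else series
    day = values.index.floor("D")
    return values.groupby(day).max().rename("day_max")


def sri(
    day_max_seq: pd.Series, spurious_threshold: float = SPURIOUS_THRESHOLD_UM
) -> pd.DataFrame:
    """Daily SRI from a day-maximum sequence.

    Returns a frame indexed by consecutive dates with columns ``day_max``,
    ``sri`` and ``basis`` ('ok' | 'no_previous_max' | 'spurious').  Rules,
    in order: either endpoint missing -> missing (no_previous_max); signed
    difference > threshold -> missing (spurious; exactly the threshold is
    retained); otherwise max(difference, 0).
    """
    dm = day_max_seq.astype("float64")
    dm.index = pd.DatetimeIndex(dm.index).floor("D")
    dm = dm.reindex(pd.date_range(dm.index.min(), dm.index.max(), freq="D",
                                  name="date"))
    prev = dm.shift(1)
    diff = dm - prev
    out = pd.DataFrame({"day_max": dm})
    basis = np.where(diff.isna(), "no_previous_max",
                     np.where(diff > spurious_threshold, "spurious", "ok"))
    vals = np.where(basis == "ok", np.maximum(diff, 0.0), np.nan)
    out["sri"] = vals
    out["basis"] = basis
    return out


def site_sri(per_tree: dict[str, pd.Series] | pd.DataFrame,
             how: str = "mean") -> pd.Series:
    """Aggregate per-tree SRI to one site series.

    The field analysis pairs a single SRI series per site with the weather
    record; the aggregation across trees (default: arithmetic mean over
    trees with a nonmissing value that day) is configurable.
    """
    wide = pd.DataFrame(per_tree)
    if how == "mean":
        agg = wide.mean(axis=1)
    elif how == "median":
        agg = wide.median(axis=1)
    else:
        raise ValueError(f"unknown aggregation: {how!r}")
    return agg.rename("sri")


def cumulative_sri(sri_seq: pd.Series) -> tuple[pd.Series, int]:
    """Progressive sum of daily SRI; missing days contribute zero to the sum
    and are counted in the returned missing-day tally."""
    cum = sri_seq.fillna(0.0).cumsum().rename("cumulative_sri")
    return cum, int(sri_seq.isna().sum())


def monthly_growth_fraction(sri_seq: pd.Series, year: int) -> pd.Series:
    """Percentage of the year's total SRI (Jan 1 - Dec 31) falling in each
    month.  Months with no nonmissing day are missing; a zero annual total
    leaves the fractions undefined (all-NaN, flagged in ``attrs``)."""
    s = sri_seq[pd.DatetimeIndex(sri_seq.index).year == year]
    if s.notna().sum() == 0:
        raise ValueError(f"no nonmissing SRI days in {year}")
    month = pd.DatetimeIndex(s.index).month
    totals = s.groupby(month).sum(min_count=1).reindex(range(1, 13))
    annual = s.sum()
    out = pd.Series(index=pd.RangeIndex(1, 13, name="month"),
                    dtype=float, name="pct_of_annual")
    if annual <= 0:
        out[:] = np.nan
        out.attrs["undefined"] = True
        return out
    out[:] = 100.0 * totals.to_numpy() / annual
    out.attrs["undefined"] = False
    return out


def growing_season(
    fractions: pd.Series, threshold: float = 5.0
) -> tuple[int, int] | None:
    """Longest run of consecutive months each strictly exceeding ``threshold``
    percent of annual growth; ties go to the earlier run; None when no month
    qualifies.  Months are January..December without wrap-around."""
    above = (fractions.reindex(range(1, 13)) > threshold).to_numpy()
    best, cur_start, best_len = None, None, 0
    for m in range(12):
        if above[m]:
            if cur_start is None:
                cur_start = m
            if m - cur_start + 1 > best_len:
                best_len = m - cur_start + 1
                best = (cur_start + 1, m + 1)
        else:
            cur_start = None
    return best


def onset_day(
    daily_tsoil: pd.Series, threshold: float = 5.0, run_days: int = 5
):
    """First date of the first run of at least ``run_days`` consecutive days
    with mean soil temperature above ``threshold``; None when the series
    never crosses.  The run requirement suppresses single-day excursions."""
    above = (daily_tsoil > threshold).to_numpy()
    n = len(above)
    for i in range(n - run_days + 1):
        if above[i:i + run_days].all():
            return daily_tsoil.index[i]
    return None


def diel_phases(
    day_readings: pd.Series,
    previous_day_max: float,
    coverage_threshold: float = 0.75,
):
    """Decompose one day's half-hourly trace into the three diel components.

    contraction: fall from the day's (first) maximum to the subsequent
    minimum; expansion: recovery from that minimum, capped at the
    contraction; increment: max(0, day_max - previous_day_max), matching
    :func:`sri`.  Returns ``(contraction, expansion, increment)`` or None
    when fewer than ``coverage_threshold`` of the 48 slots are present.
    """
    present = day_readings.dropna()
    if len(present) < coverage_threshold * SLOTS_PER_DAY:
        return None
    arr = present.to_numpy()
    imax = int(np.argmax(arr))
    day_max = arr[imax]
    after = arr[imax:]
    imin = int(np.argmin(after))
    contraction = float(day_max - after[imin])
    recovery = float(after[imin:].max() - after[imin]) if len(after) > imin else 0.0
    expansion = min(recovery, contraction)
    if previous_day_max is None or np.isnan(previous_day_max):
        increment = np.nan
    else:
        increment = max(0.0, float(day_max - previous_day_max))
    return contraction, expansion, increment


# --------------------------------------------------------------------------
# dendrometer thermal-expansion error
# --------------------------------------------------------------------------

@dataclass
class ThermalSpec:
    """Thermal expansion characteristics of a dendrometer installation.

    ``cte`` is the sensor's coefficient of thermal expansion in
    um m-1 C-1 (published values: 17 for point dendrometers, 11.2 for band
    dendrometers); ``reference_length`` is the expanding length in metres
    (the ~0.1 m sensing rod for a point sensor, the stem circumference for a
    band).  ``trunk_cte`` lets the living trunk's own (negative) expansion
    be included; published conifer values run -3 to -4 um m-1 C-1.
    """

    sensor_kind: str = "point"
    cte: float = 17.0
    reference_length: float = 0.1
    trunk_cte: float = -3.5

    @classmethod
    def point(cls, rod_length_m: float = 0.1) -> "ThermalSpec":
        return cls("point", 17.0, rod_length_m)

    @classmethod
    def band(cls, circumference_m: float = 1.0) -> "ThermalSpec":
        return cls("band", 11.2, circumference_m)

    def __post_init__(self) -> None:
        if self.cte <= 0 or self.reference_length <= 0:
            raise ValueError("cte and reference_length must be positive")


def thermal_error(
    spec: ThermalSpec, delta_t: float, include_trunk: bool = False
) -> float:
    """Apparent stem-size change (um) caused by sensor thermal expansion over
    a temperature change ``delta_t`` (C).  Sign follows ``delta_t``.  With
    ``include_trunk`` the trunk's own expansion term is added."""
    err = spec.cte * spec.reference_length * delta_t
    if include_trunk:
        err += spec.trunk_cte * spec.reference_length * delta_t
    return err
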