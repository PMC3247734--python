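"""Reading, validation and time-alignment of half-hourly logger files.

Two delimited-text layouts are supported, matching what the synthetic
generator emits:

* weather: one row per half hour, columns ``timestamp`` plus one per
  meteorological channel;
* dendrometer: long format ``timestamp, site_id, tree_id, stem_um``.

Timestamps are naive local standard time labelling the *beginning* of each
half-hour interval; there is no DST at the site.  Reading a file always
materializes the full half-hour grid between the first and last timestamp,
with explicit missing markers for absent slots, and returns a parse report
(rows read/rejected, duplicates collapsed, grid gaps, suspect values).

Stem readings are sensor-relative displacements in um, not absolute radii;
all downstream arithmetic uses differences, so the origin is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import FREQ, StemRadiusSeries

__all__ = [
    "WEATHER_COLUMNS",
    "DEFAULT_LIMITS",
    "ParseReport",
    "read_logger",
    "range_check",
    "write_weather",
    "write_stems",
    "write_ground_truth",
]

WEATHER_COLUMNS = [
    "precip", "tair", "tsoil", "soil_moisture", "rh",
    "pressure", "solrad", "wind_speed", "wind_gust",
]

# Inclusive physical-range limits; values strictly outside are flagged
# suspect (never silently dropped).  Stem step screening is deliberately
# deferred to the SRI stage (the >350 um spurious rule).
DEFAULT_LIMITS: dict[str, tuple[float, float]] = {
    "precip": (0.0, np.inf),
    "tair": (-30.0, 40.0),
    "tsoil": (-20.0, 40.0),
    "soil_moisture": (0.0, 100.0),
    "rh": (0.0, 100.0),
    "pressure": (450.0, 1100.0),
    "solrad": (0.0, np.inf),
    "wind_speed": (0.0, 300.0),
    "wind_gust": (0.0, 400.0),
}


@dataclass
class ParseReport:
    rows_read: int = 0
    rows_rejected: int = 0
    duplicates: int = 0
    gaps: int = 0
    suspect: dict = field(default_factory=dict)


class IngestError(ValueError):
    """File-level ingest failure (empty file, missing declared columns)."""


def _full_grid(index: pd.DatetimeIndex) -> pd.DatetimeIndex:
    return pd.date_range(index.min(), index.max(), freq=FREQ, name="timestamp")


def _parse_frame(raw: pd.DataFrame, value_cols: list[str],
                 missing_token: str) -> tuple[pd.DataFrame, ParseReport]:
    report = ParseReport(rows_read=len(raw))
    ts = pd.to_datetime(raw["timestamp"], errors="coerce")
    parsed = {}
    bad_value = np.zeros(len(raw), dtype=bool)
    for c in value_cols:
        col = raw[c].astype("string")
        col = col.where(col.str.strip() != missing_token if missing_token else col.str.strip() != "")
        num = pd.to_numeric(col, errors="coerce").astype("float64")
        bad_value |= (col.notna() & num.isna()).to_numpy()
        parsed[c] = num
    ok = ts.notna().to_numpy() & ~bad_value
    report.rows_rejected = int((~ok).sum())
    df = pd.DataFrame(parsed)
    df.index = pd.DatetimeIndex(ts)
    df = df.loc[ok]
    # duplicate timestamps: keep first occurrence, count the rest
    dup = df.index.duplicated(keep="first")
    report.duplicates = int(dup.sum())
    df = df.loc[~dup].sort_index()
    if df.empty:
        raise IngestError("no parseable rows in file")
    grid = _full_grid(df.index)
    on_grid = df.index.isin(grid)
    report.rows_rejected += int((~on_grid).sum())
    df = df.loc[on_grid].reindex(grid)
    report.gaps = int(df.isna().all(axis=1).sum())
    return df, report


def read_logger(
    path,
    kind: str = "weather",
    delimiter: str = ",",
    missing_token: str = "",
):
    """Parse a logger file onto the half-hour grid.

    ``kind='weather'`` returns ``(DataFrame, ParseReport)``;
    ``kind='stem'`` returns ``(list[StemRadiusSeries], ParseReport)``.

    Rows with an unparseable timestamp or a non-numeric value are rejected
    and counted; duplicated timestamps keep the first occurrence; absent grid
    slots appear as missing.  Weather relative humidity outside [0, 100] is
    flagged suspect and treated as missing (counted in the report).
    """
    try:
        raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise IngestError(f"empty logger file: {path}") from exc
    if raw.empty:
        raise IngestError(f"logger file has no data rows: {path}")

    if kind == "weather":
        missing_cols = [c for c in ["timestamp", *WEATHER_COLUMNS] if c not in raw.columns]
        if missing_cols:
            raise IngestError(f"missing declared columns: {missing_cols}")
        df, report = _parse_frame(raw, WEATHER_COLUMNS, missing_token)
        flags, counts = range_check(df, {"rh": DEFAULT_LIMITS["rh"]})
        for c in flags.columns:
            df.loc[flags[c], c] = np.nan
        report.suspect = counts
        return df, report

    if kind == "stem":
        needed = ["timestamp", "site_id", "tree_id", "stem_um"]
        missing_cols = [c for c in needed if c not in raw.columns]
        if missing_cols:
            raise IngestError(f"missing declared columns: {missing_cols}")
        report = ParseReport(rows_read=len(raw))
        series_out: list[StemRadiusSeries] = []
        for (site, tree), grp in raw.groupby(["site_id", "tree_id"], sort=True):
            sub, rep = _parse_frame(grp, ["stem_um"], missing_token)
            report.rows_rejected += rep.rows_rejected
            report.duplicates += rep.duplicates
            report.gaps += rep.gaps
            vals = sub["stem_um"]
            vals.name = "stem_um"
            flags = pd.Series(np.where(vals.isna(), "missing", "ok"),
                              index=vals.index, name="flag")
            series_out.append(StemRadiusSeries(str(tree), str(site), vals, flags))
        if not series_out:
            raise IngestError("no parseable stem rows")
        return series_out, report

    raise ValueError(f"unknown logger kind: {kind!r}")


def range_check(
    records: pd.DataFrame,
    limits: dict[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Flag out-of-range values as suspect (inclusive bounds; a value equal
    to a limit is in range).  Returns a boolean flag frame aligned with the
    checked columns and a per-channel count of flags.  Values are not
    modified or dropped."""
    if limits is None:
        limits = DEFAULT_LIMITS
    cols = [c for c in limits if c in records.columns]
    flags = pd.DataFrame(False, index=records.index, columns=cols)
    counts: dict[str, int] = {}
    for c in cols:
        lo, hi = limits[c]
        bad = records[c].notna() & ((records[c] < lo) | (records[c] > hi))
        flags[c] = bad
        counts[c] = int(bad.sum())
    return flags, counts


# --------------------------------------------------------------------------
# writers (the same delimited format read_logger consumes)
# --------------------------------------------------------------------------

def write_weather(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    out = df.copy()
    out.insert(0, "timestamp", out.index.strftime("%Y-%m-%dT%H:%M:%S"))
    out.to_csv(path, sep=delimiter, index=False)


def write_stems(series: list[StemRadiusSeries], path, delimiter: str = ",") -> None:
    frames = []
    for s in series:
        frames.append(pd.DataFrame({
            "timestamp": s.values.index.strftime("%Y-%m-%dT%H:%M:%S"),
            "site_id": s.site_id,
            "tree_id": s.tree_id,
            "stem_um": s.values.to_numpy(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep=delimiter, index=False)


def write_ground_truth(truth: pd.DataFrame, path, delimiter: str = ",") -> None:
    out = truth.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep=delimiter, index=False)
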