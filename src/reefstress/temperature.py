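"""Temperature-logger ingestion and daily quality-controlled summaries.

Hourly in-situ seawater temperatures (HOBO-style CSV exports) are parsed
into a :class:`TemperatureSeries`, aggregated to per-day summaries (mean,
max, min, daily temperature range) with a minimum-observations QC flag,
and aligned day-by-day between two years for paired tests.

The day boundary is the local calendar midnight of the logger's own
clock; no timezone arithmetic is applied.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, EmptyPairingError, FormatError

__all__ = [
    "LoggerDialect",
    "HOBO_DIALECT",
    "TemperatureSeries",
    "read_logger_csv",
    "daily_summaries",
    "align_years",
    "write_daily_csv",
]

#: Default sanity band for raw temperatures (°C); readings outside raise.
SANITY_BAND = (-5.0, 45.0)

#: Default minimum hourly observations for a day to pass QC.
MIN_OBS_DEFAULT = 20


@dataclass(frozen=True)
class LoggerDialect:
    """How to read one logger export format.

    Parameters
    ----------
    timestamp_column : str
        Header of the timestamp column.
    temp_column : str
        Header of the temperature column (°C).
    timestamp_format : str or None
        ``strftime``-style format; ``None`` lets pandas infer.
    decimal : str
        Decimal separator used in the temperature column.
    """

    timestamp_column: str = "timestamp"
    temp_column: str = "temp"
    timestamp_format: str | None = None
    decimal: str = "."


#: Preset for HOBO logger exports.
HOBO_DIALECT = LoggerDialect(
    timestamp_column="Date Time",
    temp_column="Temp",
    timestamp_format=None,
)


@dataclass
class TemperatureSeries:
    """Hourly (or finer) temperatures at one site.

    ``data`` is a float Series indexed by a strictly increasing
    DatetimeIndex; gaps are permitted.  ``accuracy_label`` carries logger
    accuracy metadata as a label only — no correction is applied.
    """

    site: str
    data: pd.Series
    accuracy_label: str | None = None
    sanity_band: tuple[float, float] = field(default=SANITY_BAND)

    def __post_init__(self):
        if len(self.data) == 0:
            raise EmptyInputError(f"temperature series for {self.site!r} is empty")
        if not isinstance(self.data.index, pd.DatetimeIndex):
            raise TypeError("TemperatureSeries.data must have a DatetimeIndex")
        if not self.data.index.is_monotonic_increasing or self.data.index.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")
        vals = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("temperatures must be finite")
        lo, hi = self.sanity_band
        bad = (vals < lo) | (vals > hi)
        if bad.any():
            t = self.data.index[bad][0]
            raise ValueError(
                f"temperature outside sanity band {self.sanity_band} at {t}"
            )

    def __len__(self):
        return len(self.data)


def read_logger_csv(
    path,
    dialect: LoggerDialect = LoggerDialect(),
    site: str | None = None,
    sanity_band: tuple[float, float] = SANITY_BAND,
) -> TemperatureSeries:
    """Read a logger CSV export into a :class:`TemperatureSeries`.

    Rows are sorted by time.  Duplicate timestamps are collapsed to their
    mean with a warning.  An unparseable timestamp raises
    :class:`~reefstress.errors.FormatError` naming the line; an empty file
    raises :class:`~reefstress.errors.EmptyInputError`.
    """
    df = pd.read_csv(path, decimal=dialect.decimal)
    if dialect.timestamp_column not in df.columns:
        raise FormatError(
            f"{path}: missing timestamp column {dialect.timestamp_column!r}"
        )
    if dialect.temp_column not in df.columns:
        raise FormatError(f"{path}: missing temperature column {dialect.temp_column!r}")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")

    ts = pd.to_datetime(
        df[dialect.timestamp_column],
        format=dialect.timestamp_format,
        errors="coerce",
    )
    if ts.isna().any():
        # +2: one for the header, one for 0-based positions
        line = int(np.flatnonzero(ts.isna().to_numpy())[0]) + 2
        raise FormatError(
            f"{path}: unparseable timestamp on line {line}: "
            f"{df[dialect.timestamp_column].iloc[line - 2]!r}"
        )
    temp = pd.to_numeric(df[dialect.temp_column], errors="coerce")
    if temp.isna().any():
        line = int(np.flatnonzero(temp.isna().to_numpy())[0]) + 2
        raise FormatError(f"{path}: unparseable temperature on line {line}")

    s = pd.Series(temp.to_numpy(dtype=float), index=pd.DatetimeIndex(ts))
    s = s.sort_index()
    if s.index.has_duplicates:
        ndup = int(s.index.duplicated().sum())
        warnings.warn(
            f"{path}: {ndup} duplicate timestamps collapsed to their mean",
            stacklevel=2,
        )
        s = s.groupby(level=0).mean()
    return TemperatureSeries(
        site=site or str(path), data=s, sanity_band=sanity_band
    )


def daily_summaries(series: TemperatureSeries, min_obs: int = MIN_OBS_DEFAULT) -> pd.DataFrame:
    """Aggregate a temperature series to per-day summaries.

    Returns a DataFrame indexed by calendar date with columns
    ``mean_temp, max_temp, min_temp, dtr, n_obs, valid``.  One row per
    date that has at least one observation; days with fewer than
    ``min_obs`` observations are kept but flagged ``valid=False`` (short
    logger days at deployment/retrieval are flagged, never silently
    dropped).
    """
    s = series.data
    grp = s.groupby(s.index.date)
    out = pd.DataFrame(
        {
            "mean_temp": grp.mean(),
            "max_temp": grp.max(),
            "min_temp": grp.min(),
            "n_obs": grp.size(),
        }
    )
    out["dtr"] = out["max_temp"] - out["min_temp"]
    out["valid"] = out["n_obs"] >= min_obs
    out = out[["mean_temp", "max_temp", "min_temp", "dtr", "n_obs", "valid"]]
    out.index = pd.Index(out.index, name="date")
    return out


def _restrict_window(daily: pd.DataFrame, window) -> pd.DataFrame:
    """Keep rows whose (month, day) falls inside ``window`` = ((m,d),(m,d))."""
    if window is None:
        return daily
    (m0, d0), (m1, d1) = window
    md = np.array([(d.month, d.day) for d in daily.index])
    lo, hi = (m0, d0), (m1, d1)
    keys = [tuple(x) for x in md]
    if lo <= hi:
        mask = np.array([lo <= k <= hi for k in keys])
    else:  # window wrapping the year boundary
        mask = np.array([k >= lo or k <= hi for k in keys])
    return daily[mask]


def align_years(
    a: pd.DataFrame,
    b: pd.DataFrame,
    window=((7, 1), (8, 31)),
    labels=("a", "b"),
) -> pd.DataFrame:
    """Pair two years of daily summaries by calendar (month, day).

    Only days valid in *both* years inside ``window`` are retained;
    Feb 29 is always dropped so every pairing unit exists in both years.
    Output is indexed by ``(month, day)`` with columns
    ``{mean,max,min,dtr}_temp_<label>`` (dtr column named ``dtr_<label>``).
    Raises :class:`~reefstress.errors.EmptyPairingError` if no day pairs.
    """
    frames = []
    for daily, lab in zip((a, b), labels):
        d = _restrict_window(daily, window)
        d = d[d["valid"]]
        md = pd.MultiIndex.from_arrays(
            [[x.month for x in d.index], [x.day for x in d.index]],
            names=["month", "day"],
        )
        d = d.set_index(md)
        d = d[~((d.index.get_level_values("month") == 2) & (d.index.get_level_values("day") == 29))]
        d = d[["mean_temp", "max_temp", "min_temp", "dtr"]].add_suffix(f"_{lab}")
        frames.append(d)
    paired = frames[0].join(frames[1], how="inner")
    if len(paired) == 0:
        raise EmptyPairingError("no days valid in both years within the window")
    return paired.sort_index()


def write_daily_csv(daily: pd.DataFrame, path) -> None:
    """Write daily summaries as CSV (date, mean, max, min, dtr, n_obs, valid)."""
    daily.to_csv(path, index_label="date")
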