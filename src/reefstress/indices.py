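"""Cumulative and acute heat-stress indices from daily temperature summaries.

The central quantity is a site-specific modified degree heating week
(mDHW): daily hotspots HS_i = STSP_i − MMM_max are accumulated over the
two warmest months whenever HS_i ≥ α (default 1 °C) and divided by 7,

    mDHW(d) = (1/7) · Σ_{i ≤ d} HS_i · [HS_i ≥ α]   (°C-week).

MMM_max is the mean of the July/August monthly means of daily mean
temperature over the study years — i.e. the summer maximum of the
bleaching years themselves, not a long-term climatology — so these
values are deliberately *not* comparable to satellite DHW products or
their bleaching-alert thresholds; they only rank heat stress between
years at the same site.

The supplementary indices (DHD, CSA, DHM, acute exceedance percentages,
max 3-day temperature, heating rate, DTR shape statistics) follow the
conventions documented on each function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyInputError, InsufficientDataError
from .temperature import _restrict_window

__all__ = [
    "ThermalConfig",
    "ThermalIndexReport",
    "compute_mmm_max",
    "hotspots",
    "compute_mdhw",
    "compute_dhd",
    "compute_csa",
    "compute_dhm",
    "compute_acute",
    "compute_max3d",
    "compute_heating_rate1",
    "dtr_stats",
    "thermal_report",
]


@dataclass
class ThermalConfig:
    """Configuration for the thermal-stress indices.

    mmm_max : climatological reference (°C), here the two-year mean of
        July/August monthly means.
    alpha : hotspot threshold (°C); only HS ≥ alpha accumulate.
    heat_window : ((month, day), (month, day)) span of the warm season.
    hotspot_basis : 'mean' or 'max' — which daily statistic defines
        STSP_i in the hotspot formula (daily mean by default; see
        docs/methods.md).
    max3d_basis : 'running_mean' or 'max_reading' for the 3-day maximum.
    """

    mmm_max: float
    alpha: float = 1.0
    heat_window: tuple = ((7, 1), (8, 31))
    hotspot_basis: str = "mean"
    max3d_basis: str = "running_mean"

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.hotspot_basis not in ("mean", "max"):
            raise ValueError("hotspot_basis must be 'mean' or 'max'")
        if self.max3d_basis not in ("running_mean", "max_reading"):
            raise ValueError("max3d_basis must be 'running_mean' or 'max_reading'")


@dataclass
class ThermalIndexReport:
    """All heat-stress indices for one year.  ``None`` marks an index
    whose value is undefined on this data; ``flags`` says why."""

    year: int
    mdhw_running: pd.Series
    mdhw_max: float
    dhd: float
    csa: float
    dhm: float
    acute1: float
    acute2: float
    max3d: float
    heating_rate1: float | None
    dtr_mean_total: float
    dtr_mean_heat: float
    dtr_skew: float | None
    dtr_kurtosis: float | None
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mdhw_running"] = {str(k): float(v) for k, v in self.mdhw_running.items()}
        return d


def _valid(daily: pd.DataFrame) -> pd.DataFrame:
    # all indices ignore QC-failed days
    return daily[daily["valid"]]


def compute_mmm_max(daily_by_year: dict, months=(7, 8)) -> float:
    """Mean over (year, month) of the monthly mean of daily mean temperature.

    ``daily_by_year`` maps year → daily-summary DataFrame.  Raises
    :class:`~reefstress.errors.InsufficientDataError` when a named month
    has no valid day in some year.
    """
    monthly_means = []
    for year, daily in daily_by_year.items():
        d = _valid(daily)
        month_of = pd.Index([x.month for x in d.index])
        for m in months:
            vals = d.loc[month_of == m, "mean_temp"]
            if len(vals) == 0:
                raise InsufficientDataError(f"no valid days in {year}-{m:02d}")
            monthly_means.append(vals.mean())
    return float(np.mean(monthly_means))


def hotspots(daily: pd.DataFrame, cfg: ThermalConfig, window="heat") -> pd.Series:
    """Daily hotspot series HS_i = STSP_i − MMM_max (°C).

    Negative values are retained; thresholding at α happens in the
    consuming indices.  ``window`` is 'heat' (cfg.heat_window), 'year'
    (no restriction) or an explicit ((m,d),(m,d)) span.
    """
    if window == "heat":
        win = cfg.heat_window
    elif window == "year":
        win = None
    else:
        win = window
    d = _valid(_restrict_window(daily, win))
    col = "mean_temp" if cfg.hotspot_basis == "mean" else "max_temp"
    hs = d[col] - cfg.mmm_max
    hs.name = "hs"
    return hs


def compute_mdhw(hs: pd.Series, cfg: ThermalConfig):
    """Modified degree heating week: running series and seasonal maximum.

    Returns ``(running, max)`` where ``running[d]`` is the cumulative sum
    of qualifying hotspots (HS ≥ α) through day *d*, divided by 7, in
    °C-week; the maximum is the final running value.
    """
    if len(hs) == 0:
        raise EmptyInputError("empty hotspot series")
    qual = hs.where(hs >= cfg.alpha, 0.0)
    running = qual.cumsum() / 7.0
    running.name = "mdhw"
    return running, float(running.iloc[-1])


def compute_dhd(daily: pd.DataFrame, cfg: ThermalConfig, window="heat") -> float:
    """Degree heating days: Σ max(0, daily mean − MMM_max), no α threshold."""
    if window == "heat":
        win = cfg.heat_window
    elif window == "year":
        win = None
    else:
        win = window
    d = _valid(_restrict_window(daily, win))
    dev = d["mean_temp"] - cfg.mmm_max
    return float(dev.clip(lower=0.0).sum())


def compute_csa(hs: pd.Series, cfg: ThermalConfig) -> float:
    """Cumulative thermal anomaly: trapezoidal integral (unit day spacing)
    of the hotspot series with sub-α values set to 0 (°C-days)."""
    if len(hs) == 0:
        raise EmptyInputError("empty hotspot series")
    if len(hs) == 1:
        warnings.warn("single-day window: CSA has no interval to integrate", stacklevel=2)
        return 0.0
    th = hs.where(hs >= cfg.alpha, 0.0).to_numpy(dtype=float)
    return float(np.trapezoid(th))


def compute_dhm(daily_year: pd.DataFrame, cfg: ThermalConfig) -> float:
    """Degree heating months: monthly hotspots MHS = monthly mean − MMM_max,
    summed over the year where MHS ≥ α (°C-month)."""
    d = _valid(daily_year)
    if len(d) == 0:
        raise EmptyInputError("no valid days")
    key = pd.Index([(x.year, x.month) for x in d.index])
    mhs = d.groupby(key)["mean_temp"].mean() - cfg.mmm_max
    return float(mhs[mhs >= cfg.alpha].sum())


def compute_acute(hs_year: pd.Series, threshold: float) -> float:
    """Percentage of valid days in the year with HS ≥ ``threshold`` (°C)."""
    if len(hs_year) == 0:
        raise EmptyInputError("no valid days for acute index")
    return float(100.0 * (hs_year >= threshold).sum() / len(hs_year))


def _consecutive_runs(dates):
    """Split a sorted date sequence into runs of consecutive calendar days."""
    runs, cur = [], [dates[0]]
    for prev, nxt in zip(dates, dates[1:]):
        if (nxt - prev).days == 1:
            cur.append(nxt)
        else:
            runs.append(cur)
            cur = [nxt]
    runs.append(cur)
    return runs


def compute_max3d(daily: pd.DataFrame, cfg: ThermalConfig) -> float:
    """Maximum temperature over any three consecutive valid days in the
    heat window.

    With ``max3d_basis='running_mean'`` (default) this is the maximum
    3-day running mean of daily means; with ``'max_reading'`` it is the
    maximum single daily-max reading inside any 3-consecutive-day run.
    """
    d = _valid(_restrict_window(daily, cfg.heat_window))
    if len(d) < 3:
        raise InsufficientDataError("need >=3 consecutive valid days for max3d")
    col = "mean_temp" if cfg.max3d_basis == "running_mean" else "max_temp"
    best = -np.inf
    for run in _consecutive_runs(list(d.index)):
        if len(run) < 3:
            continue
        vals = d.loc[run, col].to_numpy(dtype=float)
        if cfg.max3d_basis == "running_mean":
            w = np.convolve(vals, np.ones(3) / 3.0, mode="valid")
            best = max(best, float(w.max()))
        else:
            # any reading inside a >=3-day run qualifies
            best = max(best, float(vals.max()))
    if not np.isfinite(best):
        raise InsufficientDataError("no run of >=3 consecutive valid days")
    return best


def compute_heating_rate1(daily: pd.DataFrame, cfg: ThermalConfig, window="heat") -> float | None:
    """DHD divided by the number of days with daily mean above MMM_max
    (°C/day); ``None`` (flagged undefined) when no day exceeds."""
    if window == "heat":
        win = cfg.heat_window
    elif window == "year":
        win = None
    else:
        win = window
    d = _valid(_restrict_window(daily, win))
    exceed = (d["mean_temp"] > cfg.mmm_max).sum()
    if exceed == 0:
        return None
    dev = (d["mean_temp"] - cfg.mmm_max).clip(lower=0.0)
    return float(dev.sum() / exceed)


def dtr_stats(daily: pd.DataFrame, window=None):
    """Mean, skew and excess kurtosis of the daily temperature range.

    Skew is g1 = m3/m2^1.5 and kurtosis the excess g2 = m4/m2² − 3, with
    population central moments (divisor n).  On constant DTR (m2 = 0), or
    with fewer than 3 (skew) / 4 (kurtosis) valid days, the shape
    statistics are ``None``.
    """
    d = _valid(_restrict_window(daily, window))
    if len(d) == 0:
        raise EmptyInputError("no valid days for DTR stats")
    x = d["dtr"].to_numpy(dtype=float)
    mean = float(x.mean())
    if len(x) < 3 or np.ptp(x) == 0.0:
        return mean, None, None
    skew = float(stats.skew(x, bias=True))
    kurt = float(stats.kurtosis(x, fisher=True, bias=True)) if len(x) >= 4 else None
    return mean, skew, kurt


def thermal_report(daily_year: pd.DataFrame, cfg: ThermalConfig, year: int) -> ThermalIndexReport:
    """Assemble the full index suite for one year of daily summaries."""
    flags = []
    hs_heat = hotspots(daily_year, cfg, window="heat")
    hs_year = hotspots(daily_year, cfg, window="year")
    running, mdhw_max = compute_mdhw(hs_heat, cfg)
    hr1 = compute_heating_rate1(daily_year, cfg)
    if hr1 is None:
        flags.append("heating_rate1 undefined: no day above MMM_max")
    dtr_mean_total, dtr_skew, dtr_kurt = dtr_stats(daily_year)
    if dtr_skew is None:
        flags.append("dtr skew/kurtosis undefined")
    dtr_mean_heat, _, _ = dtr_stats(daily_year, window=cfg.heat_window)
    return ThermalIndexReport(
        year=year,
        mdhw_running=running,
        mdhw_max=mdhw_max,
        dhd=compute_dhd(daily_year, cfg),
        csa=compute_csa(hs_heat, cfg),
        dhm=compute_dhm(daily_year, cfg),
        acute1=compute_acute(hs_year, 1.0),
        acute2=compute_acute(hs_year, 2.0),
        max3d=compute_max3d(daily_year, cfg),
        heating_rate1=hr1,
        dtr_mean_total=dtr_mean_total,
        dtr_mean_heat=dtr_mean_heat,
        dtr_skew=dtr_skew,
        dtr_kurtosis=dtr_kurt,
        flags=flags,
    )
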