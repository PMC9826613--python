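"""Colony bookkeeping: sizes, growth, bleaching states, mortality, groups.

A cohort of *Acropora* colonies is followed over three April/May size
surveys (2016, 2017, 2018) and two September bleaching surveys (2016,
2017).  Bleaching is an ordered state UB < PB < CB (unbleached,
partially, completely bleached; "partial" includes a uniformly pale
colony).  Mortality is scored per interval t1 = Apr 2016–Apr 2017 and
t2 = Apr 2017–May 2018 as whole (entire colony dead) or partial (part
died, living tissue remained) — mutually exclusive within an interval.

Colony size enters the models as the natural log of the mean diameter
MD = 2·sqrt(PA/π) from the planar area PA (circular-colony assumption);
the t1 growth rate is (PA2017 − PA2016)/PA2016, so 0 means no change
and negative values reflect partial mortality.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "ColonyRecord",
    "STATES",
    "TIMEPOINTS",
    "INTERVALS",
    "mean_diameter",
    "growth_rate",
    "assign_group",
    "bleaching_rate_table",
    "trajectory_table",
    "mortality_status",
    "model_frame",
    "read_colony_csv",
    "records_to_frame",
    "frame_to_records",
]

log = logging.getLogger(__name__)

STATES = ("UB", "PB", "CB")
STATE_CODE = {s: i for i, s in enumerate(STATES)}
TIMEPOINTS = ("apr2016", "apr2017", "may2018")
INTERVALS = {"t1": ("apr2016", "apr2017"), "t2": ("apr2017", "may2018")}
#: Years with a September bleaching survey, and the preceding size survey.
BLEACH_YEARS = {2016: "apr2016", 2017: "apr2017"}

#: Named taxonomic groups; everything else (or any named group smaller
#: than ``min_n``) is pooled into "others".
NAMED_GROUPS = ("A. digitifera", "A. gemmifera", "tabular")
MIN_SIZE_CM = 3.0  # colonies below this mean diameter at first sighting are excluded


@dataclass
class ColonyRecord:
    """One colony's sizes, states and fates across the study."""

    colony_id: str
    species: str
    form: str  # corymbose | digitate | tabular | arborescent | unknown
    pa: dict = field(default_factory=dict)  # timepoint -> planar area cm^2
    bleaching: dict = field(default_factory=dict)  # year -> UB/PB/CB
    alive: dict = field(default_factory=dict)  # timepoint -> bool
    whole_mortality: dict = field(default_factory=dict)  # interval -> 0/1
    partial_mortality: dict = field(default_factory=dict)  # interval -> 0/1
    group: str | None = None

    def validate(self):
        for year, state in self.bleaching.items():
            if state not in STATES:
                raise ValueError(f"{self.colony_id}: bad state {state!r} in {year}")
        for iv in self.whole_mortality:
            if self.whole_mortality.get(iv, 0) and self.partial_mortality.get(iv, 0):
                raise ValueError(
                    f"{self.colony_id}: whole and partial mortality both set in {iv}"
                )
            if self.whole_mortality.get(iv, 0):
                start, end = INTERVALS[iv]
                if not self.alive.get(start, False) or self.alive.get(end, True):
                    raise ValueError(
                        f"{self.colony_id}: whole mortality in {iv} inconsistent with alive flags"
                    )
        for tp, area in self.pa.items():
            if self.alive.get(tp, False) and not (area > 0):
                raise ValueError(f"{self.colony_id}: nonpositive area at {tp}")
        return self


def mean_diameter(pa: float) -> float:
    """Mean diameter (cm) of a circular colony of planar area ``pa`` (cm²)."""
    if not pa > 0:
        raise DomainError(f"planar area must be positive, got {pa}")
    return 2.0 * math.sqrt(pa / math.pi)


def growth_rate(pa_start: float, pa_end: float) -> float:
    """Relative area change (PA_end − PA_start)/PA_start.

    0 means the colony neither grew nor shrank; negative values indicate
    shrinkage (partial mortality), positive values growth.
    """
    if not pa_start > 0:
        raise DomainError(f"starting planar area must be positive, got {pa_start}")
    return (pa_end - pa_start) / pa_start


def assign_group(records, min_n: int = 9):
    """Attach analysis group labels in place and return the records.

    Groups are the named taxa ('A. digitifera', 'A. gemmifera', tabular
    form) plus 'others'; any named group with fewer than ``min_n``
    colonies collapses into 'others'.
    """
    records = list(records)
    for r in records:
        if r.species in ("A. digitifera", "A. gemmifera"):
            r.group = r.species
        elif r.form == "tabular":
            r.group = "tabular"
        else:
            r.group = "others"
    counts = pd.Series([r.group for r in records]).value_counts()
    for g in NAMED_GROUPS:
        if counts.get(g, 0) < min_n:
            for r in records:
                if r.group == g:
                    r.group = "others"
    return records


def _groups_present(records):
    seen = []
    for g in list(NAMED_GROUPS) + ["others"]:
        if any(r.group == g for r in records):
            seen.append(g)
    return seen


def bleaching_rate_table(records, year: int) -> pd.DataFrame:
    """Per-group complete/partial/total bleaching percentages for one year.

    Denominators are the colonies with a recorded state at that year's
    September survey.  Includes a pooled 'all' row.  Percentages are
    unrounded; round at presentation time.
    """
    rows = {}
    scored = [r for r in records if year in r.bleaching]
    for g in _groups_present(scored) + ["all"]:
        sub = scored if g == "all" else [r for r in scored if r.group == g]
        n = len(sub)
        if n == 0:
            continue
        cb = sum(r.bleaching[year] == "CB" for r in sub)
        pb = sum(r.bleaching[year] == "PB" for r in sub)
        rows[g] = {
            "n": n,
            "complete_pct": 100.0 * cb / n,
            "partial_pct": 100.0 * pb / n,
            "total_pct": 100.0 * (cb + pb) / n,
        }
    out = pd.DataFrame(rows).T
    out.index.name = "group"
    out["n"] = out["n"].astype(int)
    return out


def trajectory_table(records) -> pd.DataFrame:
    """Bleaching-trajectory percentages (state 2016 → state 2017) per group.

    Denominators are per-group colonies alive (scored) in both years;
    the nine transition cells sum to 100 % in each row.  Includes a
    pooled 'all' row.
    """
    both = [r for r in records if 2016 in r.bleaching and 2017 in r.bleaching]
    cells = [f"{s0}->{s1}" for s0 in STATES for s1 in STATES]
    rows = {}
    for g in _groups_present(both) + ["all"]:
        sub = both if g == "all" else [r for r in both if r.group == g]
        n = len(sub)
        if n == 0:
            continue
        row = {c: 0.0 for c in cells}
        for r in sub:
            row[f"{r.bleaching[2016]}->{r.bleaching[2017]}"] += 100.0 / n
        row["n"] = n
        rows[g] = row
    out = pd.DataFrame(rows).T
    out.index.name = "group"
    out["n"] = out["n"].astype(int)
    return out[["n"] + cells]


def mortality_status(record: ColonyRecord, interval: str):
    """(whole, partial) 0/1 flags for one interval, or ``None`` when the
    colony was already dead at the interval start (excluded from the
    risk set, never silently scored (0, 0))."""
    start, _end = INTERVALS[interval]
    if not record.alive.get(start, False):
        return None
    return (
        int(record.whole_mortality.get(interval, 0)),
        int(record.partial_mortality.get(interval, 0)),
    )


def _size_at(record, timepoint):
    pa = record.pa.get(timepoint)
    if pa is None or not pa > 0:
        return None
    return math.log(mean_diameter(pa))


def model_frame(records, response: str) -> pd.DataFrame:
    """Build the analysis table for one response.

    ``response`` ∈ {'bleaching', 'bleaching2017', 'whole_mortality',
    'partial_mortality'}:

    * ``bleaching`` — colony×year rows (2016 and 2017) for colonies
      scored in both years; ``y`` is the ordinal state code, covariates
      ``size`` (ln MD at the preceding April), ``time`` (0/1), ``group``.
    * ``bleaching2017`` — one row per colony scored in both years; ``y``
      is the 2017 state, covariates ``size`` (Apr 2017), ``growth`` (t1
      relative area change), ``group``.
    * ``whole_mortality`` / ``partial_mortality`` — colony×interval rows
      with the 0/1 outcome; whole mortality uses every colony alive at
      the interval start, partial mortality only colonies that survived
      the interval.  Covariates ``size`` (ln MD at interval start),
      ``time`` (0 = t1, 1 = t2), ``group``.

    Rows with a missing covariate are dropped; the count is logged.
    """
    rows = []
    dropped = 0
    if response == "bleaching":
        for r in records:
            if not (2016 in r.bleaching and 2017 in r.bleaching):
                continue
            for year in (2016, 2017):
                size = _size_at(r, BLEACH_YEARS[year])
                if size is None:
                    dropped += 1
                    continue
                rows.append(
                    {
                        "colony_id": r.colony_id,
                        "y": STATE_CODE[r.bleaching[year]],
                        "size": size,
                        "time": float(year - 2016),
                        "group": r.group,
                    }
                )
    elif response == "bleaching2017":
        for r in records:
            if not (2016 in r.bleaching and 2017 in r.bleaching):
                continue
            size = _size_at(r, "apr2017")
            pa0, pa1 = r.pa.get("apr2016"), r.pa.get("apr2017")
            if size is None or pa0 is None or pa1 is None or not pa0 > 0:
                dropped += 1
                continue
            rows.append(
                {
                    "colony_id": r.colony_id,
                    "y": STATE_CODE[r.bleaching[2017]],
                    "size": size,
                    "growth": growth_rate(pa0, pa1),
                    "group": r.group,
                }
            )
    elif response in ("whole_mortality", "partial_mortality"):
        for r in records:
            for k, iv in enumerate(INTERVALS):
                status = mortality_status(r, iv)
                if status is None:
                    continue
                whole, partial = status
                if response == "partial_mortality" and whole:
                    continue  # partial-mortality risk set is interval survivors
                size = _size_at(r, INTERVALS[iv][0])
                if size is None:
                    dropped += 1
                    continue
                rows.append(
                    {
                        "colony_id": r.colony_id,
                        "y": whole if response == "whole_mortality" else partial,
                        "size": size,
                        "time": float(k),
                        "group": r.group,
                    }
                )
    else:
        raise ValueError(f"unknown response {response!r}")
    if dropped:
        log.info("model_frame(%s): dropped %d rows with missing covariates", response, dropped)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV schema (versioned header, documented in docs/methods.md)

_CSV_COLUMNS = [
    "colony_id",
    "species",
    "form",
    "pa_apr2016",
    "pa_apr2017",
    "pa_may2018",
    "bleach_2016",
    "bleach_2017",
    "alive_apr2016",
    "alive_apr2017",
    "alive_may2018",
    "whole_mortality_t1",
    "whole_mortality_t2",
    "partial_mortality_t1",
    "partial_mortality_t2",
]


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "colony_id": r.colony_id,
                "species": r.species,
                "form": r.form,
                "pa_apr2016": r.pa.get("apr2016"),
                "pa_apr2017": r.pa.get("apr2017"),
                "pa_may2018": r.pa.get("may2018"),
                "bleach_2016": r.bleaching.get(2016),
                "bleach_2017": r.bleaching.get(2017),
                "alive_apr2016": int(r.alive.get("apr2016", False)),
                "alive_apr2017": int(r.alive.get("apr2017", False)),
                "alive_may2018": int(r.alive.get("may2018", False)),
                "whole_mortality_t1": r.whole_mortality.get("t1"),
                "whole_mortality_t2": r.whole_mortality.get("t2"),
                "partial_mortality_t1": r.partial_mortality.get("t1"),
                "partial_mortality_t2": r.partial_mortality.get("t2"),
            }
        )
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def frame_to_records(df: pd.DataFrame, min_size_cm: float = MIN_SIZE_CM):
    """Parse the colony CSV schema into validated records.

    Colonies smaller than ``min_size_cm`` mean diameter at their first
    measured timepoint are excluded at ingest.
    """
    records = []
    excluded = 0
    for _, row in df.iterrows():
        pa = {}
        for tp in TIMEPOINTS:
            v = row.get(f"pa_{tp}")
            if v is not None and not pd.isna(v):
                pa[tp] = float(v)
        bleaching = {}
        for year in (2016, 2017):
            v = row.get(f"bleach_{year}")
            if isinstance(v, str) and v:
                bleaching[year] = v
        alive = {tp: bool(row.get(f"alive_{tp}", 0)) for tp in TIMEPOINTS}
        wm, pm = {}, {}
        for iv in INTERVALS:
            v = row.get(f"whole_mortality_{iv}")
            if v is not None and not pd.isna(v):
                wm[iv] = int(v)
            v = row.get(f"partial_mortality_{iv}")
            if v is not None and not pd.isna(v):
                pm[iv] = int(v)
        rec = ColonyRecord(
            colony_id=str(row["colony_id"]),
            species=str(row["species"]),
            form=str(row["form"]),
            pa=pa,
            bleaching=bleaching,
            alive=alive,
            whole_mortality=wm,
            partial_mortality=pm,
        ).validate()
        first_pa = next((pa[tp] for tp in TIMEPOINTS if tp in pa), None)
        if first_pa is not None and mean_diameter(first_pa) < min_size_cm:
            excluded += 1
            continue
        records.append(rec)
    if excluded:
        log.info("excluded %d colonies below %.1f cm mean diameter", excluded, min_size_cm)
    return records


def read_colony_csv(path, min_size_cm: float = MIN_SIZE_CM):
    """Read the colony survey CSV into validated :class:`ColonyRecord`s."""
    return frame_to_records(pd.read_csv(path), min_size_cm=min_size_cm)
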