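"""Quality control and aggregation of half-hourly station records.

Records arrive as a tidy frame (``timestamp, site, position, variable,
value``) and are regularised onto the common time grid per (site, position,
variable) series.  Outliers are screened with a global mean ± 3 SD rule
computed once on the raw record (the historical manual-inspection step is
replaced by automatic exclusion, which is logged); aggregation to daily or
ISO-week bins uses only unflagged values and masks bins with insufficient
completeness so daily extremes are not biased by logger gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

FLAG_OK = "ok"
FLAG_GAP = "gap"
FLAG_OUTLIER = "outlier"

SEASON_MONTHS = {
    "JJA": (6, 7, 8),
    "DJF": (12, 1, 2),
    "GS": (5, 6, 7, 8, 9),
}


@dataclass(frozen=True)
class CleanSeries:
    """One (site, position, variable) series on a regular time grid."""

    site: str
    position: str
    variable: str
    frame: pd.DataFrame          # index: grid timestamps; columns: value, flag
    screened: bool = False

    @property
    def key(self):
        return (self.site, self.position, self.variable)

    def ok_values(self) -> pd.Series:
        f = self.frame
        return f.loc[f["flag"] == FLAG_OK, "value"]

    def n_flagged(self, flag: str) -> int:
        return int((self.frame["flag"] == flag).sum())


def series_from_records(records: pd.DataFrame,
                        step_minutes: int = 30) -> dict[tuple, CleanSeries]:
    """Split tidy records into per-key :class:`CleanSeries` on a shared grid.

    The grid spans the earliest to the latest timestamp present, at
    ``step_minutes``; slots without a record are flagged ``gap``.
    """
    req = {"timestamp", "site", "position", "variable", "value"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"records are missing columns: {sorted(missing)}")
    if records.empty:
        raise ValueError("no records")
    ts = pd.to_datetime(records["timestamp"])
    grid = pd.date_range(ts.min(), ts.max(), freq=f"{step_minutes}min")
    out = {}
    for key, grp in records.groupby(["site", "position", "variable"],
                                    sort=True):
        vals = pd.Series(grp["value"].to_numpy(),
                         index=pd.to_datetime(grp["timestamp"]))
        vals = vals[~vals.index.duplicated()]
        aligned = vals.reindex(grid)
        flag = np.where(aligned.isna(), FLAG_GAP, FLAG_OK)
        frame = pd.DataFrame({"value": aligned.to_numpy(), "flag": flag},
                             index=grid)
        out[key] = CleanSeries(site=key[0], position=key[1],
                               variable=key[2], frame=frame)
    return out


def screen_outliers(series: CleanSeries) -> CleanSeries:
    """Flag values outside mean ± 3 SD of the full raw record.

    Mean and SD are computed once, on all unflagged values — the screen is
    deliberately non-iterative, and re-screening an already screened series
    is a no-op (flags persist; statistics are not recomputed on the
    truncated record).
    """
    if series.screened:
        return series
    vals = series.ok_values()
    if vals.size == 0:
        raise ValueError(f"series {series.key} has no usable values")
    if vals.size < 10:
        raise ValueError(
            f"series {series.key}: need >= 10 values to screen, "
            f"got {vals.size}")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    frame = series.frame.copy()
    if sd > 0:
        bad = (frame["flag"] == FLAG_OK) & (
            (frame["value"] < mean - 3.0 * sd)
            | (frame["value"] > mean + 3.0 * sd))
        frame.loc[bad, "flag"] = FLAG_OUTLIER
    return dc_replace(series, frame=frame, screened=True)


_PERIODS = ("halfhour", "day", "iso_week")


def aggregate(series: CleanSeries, period: str = "day",
              min_completeness: float = 0.9) -> pd.DataFrame:
    """Mean/min/max per bin over unflagged values.

    Returns a frame indexed by bin start with columns ``mean, min, max, n,
    completeness``; bins whose share of usable grid slots falls below
    ``min_completeness`` keep their completeness but carry missing
    statistics.  Completeness is measured against the number of grid slots
    in the bin, so gaps and flagged outliers both count against it.
    """
    if period not in _PERIODS:
        raise ValueError(f"period must be one of {_PERIODS}")
    f = series.frame
    if period == "halfhour":
        keys = f.index.floor("30min")
    elif period == "day":
        keys = f.index.normalize()
    else:
        iso = f.index.isocalendar()
        keys = pd.MultiIndex.from_arrays([iso.year, iso.week],
                                         names=["iso_year", "iso_week"])
    ok = f["flag"] == FLAG_OK
    vals = f["value"].where(ok)
    grp = vals.groupby(keys)
    out = pd.DataFrame({
        "mean": grp.mean(),
        "min": grp.min(),
        "max": grp.max(),
        "n": grp.count(),
    })
    slots = pd.Series(1, index=f.index).groupby(keys).sum()
    out["completeness"] = out["n"] / slots
    low = out["completeness"] < min_completeness
    out.loc[low, ["mean", "min", "max"]] = np.nan
    return out


def select_season(summaries: pd.DataFrame, season: str,
                  months: tuple | None = None) -> pd.DataFrame:
    """Subset daily (or finer) summaries to a season by calendar month.

    ``GS`` is May 1 – Sep 30 inclusive; ``DJF`` spans the year boundary
    (December of one year with the following January/February).  A custom
    season passes ``months`` explicitly.
    """
    if months is None:
        if season not in SEASON_MONTHS:
            raise ValueError(f"unknown season {season!r}")
        months = SEASON_MONTHS[season]
    idx = summaries.index
    if isinstance(idx, pd.MultiIndex):
        raise ValueError("season selection needs a timestamp index")
    sel = summaries[idx.month.isin(months)]
    if sel.empty:
        raise ValueError(f"no data in season {season}")
    return sel
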