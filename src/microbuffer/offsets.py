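"""Below-canopy minus open-field offsets and their seasonal estimates.

The temperature offset dT is defined at matched grid slots where both
positions carry an unflagged value (negative = cooler under the canopy).
Seasonal summaries follow the campaign's estimation protocol:

* ``mean`` — half-hourly dT with an intercept-only model under nested
  month / day / hour random intercepts; the intercept is the seasonal mean
  offset and its standard error reflects the nesting.
* ``daily_max`` / ``daily_min`` — differences of per-day extremes
  (max below-canopy minus max open-field, and likewise minima), fitted with
  month-level nesting only since one value remains per day.

The hourly coupling profile regresses below-canopy on open-field
temperature separately per hour of day across a season; an hour is
"decoupled" when its slope is well below 1 (point estimate under the slope
threshold and confidence bound under 1), the configurable rule used for the
day/night decoupling classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import FLAG_OK, SEASON_MONTHS, CleanSeries, aggregate
from .stats import fit_line_ols, fit_nested_intercept_model

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OffsetEstimate:
    site: str
    variable: str
    season: str
    statistic: str            # mean | daily_max | daily_min
    mu: float                 # °C (or m3/m3 for moisture offsets)
    se: float
    n: int
    variance_components: dict


@dataclass(frozen=True)
class CouplingRule:
    """An hour counts as decoupled when slope < ``slope_threshold`` AND the
    CI upper bound stays below ``ci_upper``."""

    slope_threshold: float = 0.8
    ci_upper: float = 1.0
    z: float = 1.96


def compute_offset_series(below: CleanSeries, open_: CleanSeries) -> pd.Series:
    """Pairwise below-minus-open differences at matched unflagged slots."""
    if not below.frame.index.equals(open_.frame.index):
        common = below.frame.index.intersection(open_.frame.index)
        if common.empty:
            raise ValueError("series grids are disjoint")
        below_f = below.frame.loc[common]
        open_f = open_.frame.loc[common]
    else:
        below_f, open_f = below.frame, open_.frame
    ok = (below_f["flag"] == FLAG_OK) & (open_f["flag"] == FLAG_OK)
    n_skipped = int((~ok).sum())
    if n_skipped:
        log.info("offset series %s/%s: skipped %d unmatched slots",
                 below.site, below.variable, n_skipped)
    return (below_f.loc[ok, "value"] - open_f.loc[ok, "value"]).rename("dT")


def _nested_labels(index: pd.DatetimeIndex):
    month = index.strftime("%Y-%m")
    day = index.strftime("%Y-%m-%d")
    hour = index.strftime("%Y-%m-%d:%H")
    return month, day, hour


def _season_mask(index: pd.DatetimeIndex, season: str) -> np.ndarray:
    return index.month.isin(SEASON_MONTHS[season])


def seasonal_offset_table(below: CleanSeries, open_: CleanSeries,
                          seasons=("JJA", "DJF", "GS"),
                          statistics=("mean", "daily_max", "daily_min"),
                          min_days: int = 14,
                          min_completeness: float = 0.9,
                          ) -> list[OffsetEstimate]:
    """Seasonal offset estimates for one site/variable pair."""
    out = []
    offsets = compute_offset_series(below, open_)
    daily_b = aggregate(below, "day", min_completeness)
    daily_o = aggregate(open_, "day", min_completeness)
    for season in seasons:
        for stat in statistics:
            if stat == "mean":
                vals = offsets[_season_mask(offsets.index, season)]
                ndays = vals.index.normalize().nunique()
                if ndays < min_days:
                    raise ValueError(
                        f"season {season}: only {ndays} days of paired data")
                month, day, hour = _nested_labels(vals.index)
                fit = fit_nested_intercept_model(vals.to_numpy(),
                                                 month, day, hour)
            elif stat in ("daily_max", "daily_min"):
                col = "max" if stat == "daily_max" else "min"
                diff = (daily_b[col] - daily_o[col]).dropna()
                diff = diff[_season_mask(diff.index, season)]
                if diff.size < min_days:
                    raise ValueError(
                        f"season {season}: only {diff.size} days of "
                        f"daily extremes")
                fit = fit_nested_intercept_model(
                    diff.to_numpy(), diff.index.strftime("%Y-%m"))
            else:
                raise ValueError(f"unknown statistic {stat!r}")
            out.append(OffsetEstimate(
                site=below.site, variable=below.variable, season=season,
                statistic=stat, mu=fit.mu, se=fit.se_mu, n=fit.n,
                variance_components=dict(fit.sigma2,
                                         resid=fit.sigma2_resid)))
    return out


def hourly_coupling_profile(below: CleanSeries, open_: CleanSeries,
                            season: str = "GS",
                            rule: CouplingRule = CouplingRule(),
                            min_pairs: int = 30) -> pd.DataFrame:
    """Per-hour-of-day slope of below-canopy on open-field temperature.

    Returns a 24-row frame (``slope, se, ci_low, ci_high, n, coupled``);
    hours with fewer than ``min_pairs`` matched observations carry missing
    values rather than raising.
    """
    ok = ((below.frame["flag"] == FLAG_OK)
          & (open_.frame["flag"] == FLAG_OK)
          & _season_mask(below.frame.index, season))
    x = open_.frame.loc[ok, "value"]
    y = below.frame.loc[ok, "value"]
    hours = x.index.hour
    rows = []
    for h in range(24):
        sel = hours == h
        if sel.sum() < min_pairs:
            rows.append((h, np.nan, np.nan, np.nan, np.nan,
                         int(sel.sum()), pd.NA))
            continue
        fit = fit_line_ols(x[sel], y[sel])
        lo = fit.slope - rule.z * fit.se_slope
        hi = fit.slope + rule.z * fit.se_slope
        decoupled = (fit.slope < rule.slope_threshold) and (hi < rule.ci_upper)
        rows.append((h, fit.slope, fit.se_slope, lo, hi, fit.n,
                     not decoupled))
    df = pd.DataFrame(rows, columns=["hour", "slope", "se", "ci_low",
                                     "ci_high", "n", "coupled"])
    return df.set_index("hour")
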