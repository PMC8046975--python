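"""Soil-temperature summaries: snow-period detection and thermal amplitude.

An insulating snowpack pins soil temperature near 0 °C (the zero-curtain):
days whose mean soil temperature sits in a narrow band around zero *and*
whose diurnal amplitude is small are snow candidates; runs of consecutive
candidate days become detected snow periods.  Thermal amplitude (daily
max - min) summarises how strongly a position's soil is exposed to the
diurnal cycle, e.g. during alternating snow/no-snow spells.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import pandas as pd


@dataclass(frozen=True)
class SnowPeriod:
    site: str | None
    position: str | None
    start: date
    end: date

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("snow period start is after its end")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def overlap_days(self, start, end) -> int:
        a = max(self.start, pd.Timestamp(start).date())
        b = min(self.end, pd.Timestamp(end).date())
        return max((b - a).days + 1, 0)


def detect_snow_periods(daily: pd.DataFrame,
                        site: str | None = None,
                        position: str | None = None,
                        mean_range: tuple = (-0.5, 1.5),
                        max_amplitude: float = 1.0,
                        min_run_days: int = 3) -> list[SnowPeriod]:
    """Detect snow periods from daily soil-temperature summaries.

    ``daily`` needs columns ``mean, min, max`` on a date-like index (rows
    with missing values never qualify).  A day is a candidate when its mean
    lies inside ``mean_range`` and its amplitude (max - min) stays below
    ``max_amplitude``; runs of at least ``min_run_days`` *consecutive
    calendar days* are reported.  Loosening either threshold can only grow
    the candidate set, so detected periods are monotone in the thresholds.
    """
    amp = daily["max"] - daily["min"]
    cand = (daily["mean"].ge(mean_range[0]) & daily["mean"].le(mean_range[1])
            & amp.lt(max_amplitude)).fillna(False)
    days = pd.to_datetime(cand.index[cand]).normalize()
    periods = []
    run_start = prev = None
    for d in days:
        if prev is not None and (d - prev).days == 1:
            prev = d
            continue
        if run_start is not None:
            if (prev - run_start).days + 1 >= min_run_days:
                periods.append(SnowPeriod(site, position, run_start.date(),
                                          prev.date()))
        run_start = prev = d
    if run_start is not None and (prev - run_start).days + 1 >= min_run_days:
        periods.append(SnowPeriod(site, position, run_start.date(),
                                  prev.date()))
    return periods


def thermal_amplitude(daily: pd.DataFrame,
                      window: tuple | None = None) -> dict:
    """Per-day thermal amplitude and its window summary.

    ``window`` is an optional (start, end) date pair (end inclusive).
    Days lacking a min or max are skipped.  Returns the per-day series plus
    the window maximum and mean.
    """
    amp = (daily["max"] - daily["min"]).dropna()
    if window is not None:
        a, b = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        amp = amp[(amp.index >= a) & (amp.index <= b)]
    return {
        "per_day": amp,
        "max": float(amp.max()) if amp.size else float("nan"),
        "mean": float(amp.mean()) if amp.size else float("nan"),
        "n_days": int(amp.size),
    }
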