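"""Land-surface phenology from 16-day NDVI composites.

Start, end, and length of the growing season (SOS/EOS/LOS) are read off a
smoothed annual NDVI curve: the dormant-season (winter composite) mean sets
the baseline, the seasonal maximum the peak, and the season bounds are the
first upward and last downward crossings of baseline + a configurable
fraction (default one half) of the amplitude, located by linear
interpolation between composite dates.  LOS is defined as EOS - SOS, an
identity that holds exactly for every output (published phenology products
sometimes report LOS from a different smoothing and can violate it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter


@dataclass(frozen=True)
class PhenologyMetrics:
    sos: float          # day of year
    eos: float
    los: float          # = eos - sos
    baseline: float
    peak: float
    threshold: float

    def __post_init__(self):
        if not self.sos < self.eos:
            raise ValueError("SOS must precede EOS")


def _dormant_mask(doy: np.ndarray) -> np.ndarray:
    return (doy >= 335) | (doy <= 59)   # winter composites


def extract_phenology(ndvi, threshold_fraction: float = 0.5,
                      min_amplitude: float = 0.05,
                      smooth_window: int = 5) -> PhenologyMetrics:
    """Extract SOS/EOS/LOS from one year of 16-day NDVI composites.

    ``ndvi`` is a frame with ``doy`` and ``ndvi`` columns (as produced by
    the synthetic generator or read from CSV with a ``date`` column).
    Raises if the seasonal amplitude is below ``min_amplitude`` (no
    detectable growing season).
    """
    if isinstance(ndvi, pd.DataFrame):
        df = ndvi.copy()
        if "doy" not in df.columns:
            df["doy"] = pd.to_datetime(df["date"]).dt.dayofyear
        doy = df["doy"].to_numpy(float)
        values = df["ndvi"].to_numpy(float)
    else:
        values = np.asarray(ndvi, dtype=float)
        doy = np.arange(1, 1 + 16 * values.size, 16, dtype=float)
    if values.size < 20:
        raise ValueError("need a full year of 16-day composites")
    order = np.argsort(doy)
    doy, values = doy[order], values[order]
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must lie in (0, 1)")
    window = min(smooth_window, values.size // 2 * 2 - 1)
    smooth = savgol_filter(values, window_length=window, polyorder=2,
                           mode="interp")
    dormant = _dormant_mask(doy)
    baseline = float(smooth[dormant].mean()) if dormant.any() \
        else float(smooth.min())
    peak = float(smooth.max())
    amplitude = peak - baseline
    if amplitude < min_amplitude:
        raise ValueError(
            f"seasonal NDVI amplitude {amplitude:.3f} below "
            f"{min_amplitude}; no growing-season signal")
    thr = baseline + threshold_fraction * amplitude

    above = smooth >= thr
    sos = eos = None
    for i in range(1, above.size):
        if above[i] and not above[i - 1]:
            frac = (thr - smooth[i - 1]) / (smooth[i] - smooth[i - 1])
            x = doy[i - 1] + frac * (doy[i] - doy[i - 1])
            if sos is None:
                sos = x
        if not above[i] and above[i - 1]:
            frac = (smooth[i - 1] - thr) / (smooth[i - 1] - smooth[i])
            eos = doy[i - 1] + frac * (doy[i] - doy[i - 1])
    if sos is None or eos is None or not sos < eos:
        raise ValueError("could not locate both season bounds")
    return PhenologyMetrics(sos=float(sos), eos=float(eos),
                            los=float(eos - sos), baseline=baseline,
                            peak=peak, threshold=float(thr))
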