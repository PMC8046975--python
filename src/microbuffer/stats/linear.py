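"""Ordinary least-squares line fits with exact closed-form uncertainties.

The coupling line (below-canopy temperature regressed on open-field
temperature) and the per-hour decoupling slopes are plain two-parameter
regressions; they are solved here directly from the normal equations so the
downstream thermal-sum integration sees exact coefficients and a full
covariance for the (intercept, slope) pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LineFit:
    """A fitted line ``y = intercept + slope * x``.

    Attributes
    ----------
    intercept, slope
        Least-squares estimates (°C and °C/°C for temperature couplings).
    se_intercept, se_slope
        Classical standard errors (residual variance on ``n - 2`` df).
    resid_sd
        Residual standard deviation.
    n
        Number of complete (x, y) pairs used.
    cov_ab
        Covariance between intercept and slope estimates.
    """

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    resid_sd: float
    n: int
    cov_ab: float

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def fit_line_ols(x, y) -> LineFit:
    """Fit ``y = a + b x`` by least squares; pairs with NaN are dropped.

    Raises
    ------
    ValueError
        If fewer than 3 complete pairs remain or ``x`` has zero variance.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    xbar = x.mean()
    ybar = y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    if sxx <= 0.0:
        raise ValueError("x has zero variance; slope is not identifiable")
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    b = sxy / sxx
    a = ybar - b * xbar
    resid = y - a - b * x
    rss = float(resid @ resid)
    s2 = rss / (n - 2)
    se_b = math.sqrt(s2 / sxx)
    se_a = math.sqrt(s2 * (1.0 / n + xbar**2 / sxx))
    cov_ab = -s2 * xbar / sxx
    return LineFit(
        intercept=float(a),
        slope=float(b),
        se_intercept=se_a,
        se_slope=se_b,
        resid_sd=math.sqrt(s2),
        n=int(n),
        cov_ab=cov_ab,
    )
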