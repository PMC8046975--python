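"""Buffering capacity: thermal sum between the coupling line and the 1:1 line.

The fitted below-canopy ~ open-field line ``y = alpha + beta x`` is compared
with the identity line over the observed open-field range ``[x_min, x_max]``.
Where the line sits above the identity the canopy is warmer than the open
field; where it sits below, cooler.  The buffering capacity on each side is
the integrated thermal sum (°C, area over a °C axis) of the discrepancy

    f(x) = alpha + (beta - 1) x

split at the crossing point ``x* = alpha / (1 - beta)``.  Both areas have
closed-form quadratic antiderivatives; no numerical integration is involved
(tests cross-check against a dense trapezoid oracle).

Note that externally reported areas computed from rounded coefficients can
differ from the closed form on those same rounded coefficients; the computed
crossing point is authoritative here, with an optional override for
reproduction runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .stats import LineFit, fit_line_ols


@dataclass(frozen=True)
class BufferingResult:
    """Crossing point and signed areas for one coupling line.

    ``b_cool`` integrates where the canopy is cooler (line below identity,
    the warm side of the crossing for beta < 1); ``b_warm`` integrates where
    the canopy is warmer (cool side of the crossing).  Areas are >= 0 by
    construction; a side that does not intersect the observed range is 0
    and flagged invalid.
    """

    site: str | None
    fit: LineFit | None
    alpha: float
    beta: float
    x_star: float | None          # None when beta == 1 (lines parallel)
    x_min: float
    x_max: float
    b_cool: float
    b_warm: float
    warm_side_valid: bool
    cool_side_valid: bool


def _segment_area(alpha: float, beta: float, a: float, b: float) -> float:
    """Integral of alpha + (beta-1) x over [a, b] (signed)."""
    return alpha * (b - a) + 0.5 * (beta - 1.0) * (b * b - a * a)


def buffering_capacity(fit, x_min: float, x_max: float,
                       site: str | None = None,
                       x_star_override: float | None = None,
                       ) -> BufferingResult:
    """Compute crossing point and both thermal-sum areas in closed form.

    Parameters
    ----------
    fit
        A :class:`LineFit` or an ``(alpha, beta)`` pair.
    x_min, x_max
        Open-field integration bounds, conventionally the observed range of
        seasonal daily means.
    x_star_override
        Force the split point (for reproducing published figures whose
        printed crossing disagrees with the rounded coefficients); the areas
        remain exact integrals of the line discrepancy on each side.
    """
    if isinstance(fit, LineFit):
        alpha, beta = fit.intercept, fit.slope
        linefit = fit
    else:
        alpha, beta = (float(v) for v in fit)
        linefit = None
    for v in (alpha, beta, x_min, x_max):
        if not math.isfinite(v):
            raise ValueError("non-finite input")
    if not x_min < x_max:
        raise ValueError("x_min must be below x_max")

    if beta == 1.0:
        x_star = None
        area = abs(alpha) * (x_max - x_min)
        if alpha > 0:
            b_warm, b_cool = area, 0.0
        elif alpha < 0:
            b_warm, b_cool = 0.0, area
        else:
            b_warm = b_cool = 0.0
        return BufferingResult(site=site, fit=linefit, alpha=alpha,
                               beta=beta, x_star=None, x_min=x_min,
                               x_max=x_max, b_cool=b_cool, b_warm=b_warm,
                               warm_side_valid=alpha > 0,
                               cool_side_valid=alpha < 0)

    x_star = alpha / (1.0 - beta)
    split = x_star if x_star_override is None else float(x_star_override)
    split_clipped = min(max(split, x_min), x_max)
    left = _segment_area(alpha, beta, x_min, split_clipped)
    right = _segment_area(alpha, beta, split_clipped, x_max)
    if beta < 1.0:
        # discrepancy decreasing: canopy warmer left of the crossing
        b_warm, b_cool = max(left, 0.0), max(-right, 0.0)
        warm_valid = split > x_min
        cool_valid = split < x_max
    else:
        b_warm, b_cool = max(right, 0.0), max(-left, 0.0)
        warm_valid = split < x_max
        cool_valid = split > x_min
    return BufferingResult(site=site, fit=linefit, alpha=alpha, beta=beta,
                           x_star=x_star, x_min=x_min, x_max=x_max,
                           b_cool=b_cool, b_warm=b_warm,
                           warm_side_valid=warm_valid,
                           cool_side_valid=cool_valid)


def buffering_area_numeric(alpha: float, beta: float, x_min: float,
                           x_max: float, dx: float = 1e-4):
    """Trapezoid-rule oracle for the two areas (independent of the closed
    form; used to validate it).  The grid always contains the crossing
    point, so the piecewise-linear integrand is handled exactly up to
    floating-point rounding."""
    pts = [x_min, x_max]
    if beta != 1.0:
        xs = alpha / (1.0 - beta)
        if x_min < xs < x_max:
            pts.insert(1, xs)
    warm = cool = 0.0
    for a, b in zip(pts, pts[1:]):
        n = max(int(math.ceil((b - a) / dx)), 2)
        grid = np.linspace(a, b, n + 1)
        f = alpha + (beta - 1.0) * grid
        warm += float(np.trapezoid(np.maximum(f, 0.0), grid))
        cool += float(np.trapezoid(np.maximum(-f, 0.0), grid))
    return warm, cool


@dataclass(frozen=True)
class AncovaResult:
    """Pooled two-site comparison of coupling lines (interaction ANCOVA)."""

    slope_diff: float             # slope(site b) - slope(site a)
    se_slope_diff: float
    p_interaction: float          # H0: equal slopes
    intercept_diff: float
    p_intercept: float            # H0: equal intercepts (given interaction)
    n: int
    sites: tuple[str, str]


def compare_buffering(daily_a, daily_b, sites=("a", "b")) -> AncovaResult:
    """ANCOVA of pooled daily means: T_in ~ T_out * site.

    ``daily_a``/``daily_b`` are ``(x, y)`` pairs of open-field and
    below-canopy daily means for the two sites.  The interaction term tests
    whether the coupling slopes (hence the buffering behaviour) differ.
    """
    xa, ya = (np.asarray(v, dtype=float) for v in daily_a)
    xb, yb = (np.asarray(v, dtype=float) for v in daily_b)
    if sites[0] == sites[1]:
        raise ValueError("need two distinct sites")
    df = pd.DataFrame({
        "x": np.concatenate([xa, xb]),
        "y": np.concatenate([ya, yb]),
        "site": [str(sites[0])] * xa.size + [str(sites[1])] * xb.size,
    }).dropna()
    if df["site"].nunique() < 2:
        raise ValueError("need data from two sites")
    model = smf.ols("y ~ x * C(site)", data=df).fit()
    inter = [t for t in model.params.index if t.startswith("x:C(site)")][0]
    dummy = [t for t in model.params.index
             if t.startswith("C(site)") and ":" not in t][0]
    return AncovaResult(
        slope_diff=float(model.params[inter]),
        se_slope_diff=float(model.bse[inter]),
        p_interaction=float(model.pvalues[inter]),
        intercept_diff=float(model.params[dummy]),
        p_intercept=float(model.pvalues[dummy]),
        n=int(model.nobs),
        sites=(str(sites[0]), str(sites[1])),
    )


def coupling_line_from_daily(daily_below: pd.Series,
                             daily_open: pd.Series) -> LineFit:
    """OLS coupling line from matched daily means (convenience wrapper)."""
    joined = pd.concat([daily_open.rename("x"), daily_below.rename("y")],
                       axis=1).dropna()
    return fit_line_ols(joined["x"], joined["y"])
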