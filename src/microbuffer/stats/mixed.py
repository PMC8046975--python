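"""Mixed-effects estimators for nested station time series.

Two model families are implemented from first principles:

``fit_nested_intercept_model``
    Intercept-only model with up to three nested random-intercept levels
    (month / day-within-month / hour-within-day) plus a residual.  The
    marginal likelihood of a purely nested Gaussian model factorises level by
    level: children of a node can be collapsed onto their precision-weighted
    mean, whose variance is ``1/W + sigma2_level``.  This gives an exact O(N)
    evaluation of the (restricted) likelihood without ever forming a
    covariance matrix, so a year of half-hourly offsets fits in milliseconds.

``fit_mixed_model`` / ``fit_mixed_line``
    A general fixed-effects design with month and day-within-month random
    intercepts.  The unit-residual covariance ``V = I + g_d Zd Zd' + g_m Zm
    Zm'`` is inverted analytically by two nested rank-one (Woodbury) updates,
    which reduces GLS cross-products and log|V| to grouped sums.  The
    residual variance and fixed effects are profiled out, leaving a two
    dimensional optimisation over log variance ratios.

REML is the default, matching standard practice for variance-component
estimation; likelihood-ratio comparisons refit by ML internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

_LOG2PI = math.log(2.0 * math.pi)
_ZMIN, _ZMAX = -30.0, 15.0  # clip for log-variance parameters


# ---------------------------------------------------------------------------
# label handling
# ---------------------------------------------------------------------------

def _factorize(labels) -> np.ndarray:
    codes, _ = pd.factorize(pd.Series(list(labels)))
    if (codes < 0).any():
        raise ValueError("labels may not contain missing values")
    return codes


def _validate_nested(levels: Sequence[np.ndarray]) -> None:
    """Each label must appear under exactly one parent label."""
    for k in range(1, len(levels)):
        pairs = pd.DataFrame({"parent": levels[k - 1], "child": levels[k]})
        uniq = pairs.drop_duplicates()
        if uniq["child"].duplicated().any():
            raise ValueError(
                "labels are not nested: a level-%d label occurs under two "
                "distinct parents" % (k + 1)
            )


def _sorted_structure(code_levels: list[np.ndarray]):
    """Sort observations lexicographically and return group start indices
    (in observation space) for every nesting depth."""
    n = code_levels[0].size
    order = np.lexsort(tuple(reversed(code_levels)))
    sorted_codes = [c[order] for c in code_levels]
    starts = []
    change = np.zeros(n - 1, dtype=bool) if n > 1 else np.zeros(0, dtype=bool)
    for c in sorted_codes:
        change = change | (c[1:] != c[:-1])
        starts.append(np.flatnonzero(np.concatenate(([True], change))))
    return order, starts


# ---------------------------------------------------------------------------
# intercept-only nested model
# ---------------------------------------------------------------------------

@dataclass
class VarComp:
    """REML estimates for the intercept-only nested random-intercept model."""

    mu: float
    se_mu: float
    sigma2: dict[str, float]
    sigma2_resid: float
    loglik: float           # restricted log-likelihood at the optimum
    loglik_ml: float        # ML log-likelihood at the same variance estimates
    n: int
    level_names: tuple[str, ...]
    converged: bool = True


def _nested_m2ll(y_sorted, starts, sig2_levels, sig2_resid):
    """Return (-2 profile pieces) for the nested intercept model.

    Collapses the nesting bottom-up; returns the accumulated log-determinant
    and internal quadratic form plus the top-level means and their variances,
    from which any mu-dependent quantity follows.
    """
    n = y_sorted.size
    m = y_sorted
    v = np.full(n, sig2_resid)
    ld = 0.0
    qf = 0.0
    cur_starts = np.arange(n)
    for depth in range(len(starts) - 1, -1, -1):
        sig2 = sig2_levels[depth]
        gb = np.searchsorted(cur_starts, starts[depth])
        w = 1.0 / v
        Wg = np.add.reduceat(w, gb)
        xbar = np.add.reduceat(w * m, gb) / Wg
        counts = np.diff(np.append(gb, m.size))
        rep = np.repeat(np.arange(gb.size), counts)
        qf += float(np.sum(w * (m - xbar[rep]) ** 2))
        Vg = 1.0 / Wg + sig2
        ld += float(np.sum(np.log(v)) + np.sum(np.log1p(sig2 * Wg))
                    - np.sum(np.log(Vg)))
        m, v = xbar, Vg
        cur_starts = starts[depth]
    ld += float(np.sum(np.log(v)))
    return ld, qf, m, v


def _nested_logliks(y_sorted, starts, sig2_levels, sig2_resid):
    n = y_sorted.size
    ld, qf, m, v = _nested_m2ll(y_sorted, starts, sig2_levels, sig2_resid)
    w = 1.0 / v
    wtot = float(w.sum())
    mu = float(np.sum(w * m) / wtot)
    qf_top = float(np.sum(w * (m - mu) ** 2))
    m2ll = n * _LOG2PI + ld + qf + qf_top
    ll_ml = -0.5 * m2ll
    ll_reml = ll_ml + 0.5 * _LOG2PI - 0.5 * math.log(wtot)
    return ll_ml, ll_reml, mu, wtot


def fit_nested_intercept_model(values,
                               month_labels,
                               day_labels=None,
                               hour_labels=None,
                               method: str = "REML") -> VarComp:
    """Fit ``y = mu + a_month + b_day + c_hour + e`` by (RE)ML.

    ``day_labels`` / ``hour_labels`` are optional so the same estimator
    serves half-hourly offsets (three nested levels) and daily-extreme
    offsets (months only).  Labels must already be properly nested — a day
    label reused under two months is rejected; compose labels (for example
    ``"2016-07-15:13"`` for an hour cell) before calling.

    For balanced designs with interior optima the REML solution coincides
    with the classical nested-ANOVA method-of-moments estimators, which is
    exercised as a test oracle.
    """
    y = np.asarray(values, dtype=float).ravel()
    keep = np.isfinite(y)
    raw_levels = [np.asarray(lv, dtype=object)
                  for lv in (month_labels, day_labels, hour_labels)
                  if lv is not None]
    names = ("month", "day", "hour")[: len(raw_levels)]
    for lv in raw_levels:
        if lv.size != y.size:
            raise ValueError("labels must match values in length")
    raw_levels = [lv[keep] for lv in raw_levels]
    y = y[keep]
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 non-missing values")
    if not raw_levels:
        raise ValueError("at least one nesting level is required")
    _validate_nested(raw_levels)
    codes = [_factorize(lv) for lv in raw_levels]
    if np.unique(codes[0]).size < 2:
        raise ValueError("need at least 2 groups at the coarsest level")
    order, starts = _sorted_structure(codes)
    ys = y[order]

    vtot = float(np.var(y))
    if vtot < 1e-24:  # degenerate: a constant series
        return VarComp(mu=float(y[0]), se_mu=0.0,
                       sigma2={nm: 0.0 for nm in names}, sigma2_resid=0.0,
                       loglik=math.inf, loglik_ml=math.inf, n=n,
                       level_names=names)

    L = len(codes)
    reml = method.upper() == "REML"

    def objective(z):
        z = np.clip(z, _ZMIN, _ZMAX)
        sig2 = np.exp(z)
        ll_ml, ll_reml, _, _ = _nested_logliks(ys, starts, sig2[:L], sig2[L])
        return -(ll_reml if reml else ll_ml)

    z0 = np.full(L + 1, math.log(max(vtot, 1e-12) / (L + 1)))
    res = optimize.minimize(objective, z0, method="Nelder-Mead",
                            options=dict(xatol=1e-9, fatol=1e-11,
                                         maxiter=4000, maxfev=8000))
    # polish from the first optimum; NM restarts sharpen balanced-design fits
    res2 = optimize.minimize(objective, res.x, method="Nelder-Mead",
                             options=dict(xatol=1e-10, fatol=1e-12,
                                          maxiter=2000, maxfev=4000))
    zhat = np.clip(res2.x, _ZMIN, _ZMAX)
    sig2 = np.exp(zhat)
    floor = 1e-8 * vtot
    sig2 = np.where(sig2 < floor, 0.0, sig2)
    sig2_resid = float(max(sig2[L], floor))
    ll_ml, ll_reml, mu, wtot = _nested_logliks(ys, starts, sig2[:L],
                                               sig2_resid)
    return VarComp(
        mu=mu,
        se_mu=math.sqrt(1.0 / wtot),
        sigma2={nm: float(s) for nm, s in zip(names, sig2[:L])},
        sigma2_resid=sig2_resid,
        loglik=ll_reml,
        loglik_ml=ll_ml,
        n=n,
        level_names=names,
        converged=bool(res2.success or res.success),
    )


def balanced_nested_anova(values, month_labels, day_labels=None,
                          hour_labels=None) -> dict[str, float]:
    """Closed-form method-of-moments variance components for a *balanced*
    nested design (expected-mean-squares equations solved directly).

    Independent oracle for :func:`fit_nested_intercept_model`; it never goes
    through the likelihood code path.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float)})
    levels = [lv for lv in (month_labels, day_labels, hour_labels)
              if lv is not None]
    names = ["month", "day", "hour"][: len(levels)]
    for nm, lv in zip(names, levels):
        df[nm] = list(lv)
    L = len(names)
    # per-cell sizes (balanced by assumption)
    cell_n = df.groupby(names, sort=False)["y"].size()
    n_per_cell = int(cell_n.iloc[0])
    children = []  # number of child units per parent at each depth
    for k in range(1, L):
        cnt = df.drop_duplicates(names[: k + 1]).groupby(names[:k]).size()
        children.append(int(cnt.iloc[0]))
    grand = df["y"].mean()
    group_means = [df.groupby(names[:k], sort=False)["y"].transform("mean")
                   for k in range(1, L + 1)]
    # residual within finest cells
    ss_res = float(((df["y"] - group_means[-1]) ** 2).sum())
    n = len(df)
    n_cells = len(cell_n)
    ms_res = ss_res / (n - n_cells)
    # between-group mean squares, finest to coarsest
    out = {}
    # units per observation at each level (coefficient of that level's
    # variance in the expected mean square)
    mult = [n_per_cell]
    for c in reversed(children):
        mult.append(mult[-1] * c)
    mult = list(reversed(mult))  # coarsest first
    ms_levels = []
    for k in range(L, 0, -1):
        upper = group_means[k - 2] if k >= 2 else pd.Series(grand, index=df.index)
        ss = float(((group_means[k - 1] - upper) ** 2).sum())
        n_groups = len(df.drop_duplicates(names[:k]))
        n_upper = len(df.drop_duplicates(names[: k - 1])) if k >= 2 else 1
        ms_levels.append(ss / (n_groups - n_upper))
    ms_levels = list(reversed(ms_levels))  # coarsest first
    out["resid"] = ms_res
    prev_ms = ms_res
    for k in range(L - 1, -1, -1):
        out[names[k]] = max((ms_levels[k] - prev_ms) / mult[k], 0.0)
        prev_ms = ms_levels[k]
    return out


# ---------------------------------------------------------------------------
# fixed-effects design with month/day nested random intercepts
# ---------------------------------------------------------------------------

@dataclass
class MixedModelFit:
    """A fitted linear mixed model with month and day-in-month intercepts."""

    beta: np.ndarray
    se_beta: np.ndarray
    cov_beta: np.ndarray
    names: tuple[str, ...]
    sigma2_month: float
    sigma2_day: float
    sigma2_resid: float
    loglik: float
    method: str
    n: int
    var_fixed: float
    converged: bool = True
    _refit: dict = field(default_factory=dict, repr=False)

    @property
    def p(self) -> int:
        return self.beta.size

    def coef(self) -> dict[str, float]:
        return {nm: float(b) for nm, b in zip(self.names, self.beta)}


def _two_level_pieces(Z, day_starts, month_starts_day, n_day, gam_d, gam_m):
    """Cross-products Z' V^-1 Z and log|V| for V = I + g_d Zd Zd' + g_m Zm Zm'."""
    c_d = gam_d / (1.0 + gam_d * n_day)
    Sd = np.add.reduceat(Z, day_starts, axis=0)           # per-day col sums
    M = Z.T @ Z - (Sd * c_d[:, None]).T @ Sd
    a_m = np.add.reduceat(n_day - c_d * n_day**2, month_starts_day)
    k_m = gam_m / (1.0 + gam_m * a_m)
    U = np.add.reduceat((1.0 - c_d * n_day)[:, None] * Sd,
                        month_starts_day, axis=0)          # Z' V1^-1 1_m
    M -= (U * k_m[:, None]).T @ U
    logdetV = float(np.sum(np.log1p(gam_d * n_day))
                    + np.sum(np.log1p(gam_m * a_m)))
    return M, logdetV, c_d, k_m, Sd, U, a_m


def fit_mixed_model(y, X, month_labels, day_labels, names=None,
                    method: str = "REML") -> MixedModelFit:
    """REML/ML fit of ``y = X beta + a_month + b_day + e``.

    The residual variance and ``beta`` are profiled out analytically; the
    optimiser only sees the two log variance ratios.  When both random
    variances collapse to zero the estimates reduce to ordinary least
    squares on the same design.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    if X.shape[0] != y.size:
        raise ValueError("X and y are not conformable")
    month = np.asarray(month_labels, dtype=object)
    day = np.asarray(day_labels, dtype=object)
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X, month, day = y[keep], X[keep], month[keep], day[keep]
    n, p = X.shape
    if n <= p + 2:
        raise ValueError("too few observations for the design")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient fixed-effects design")
    _validate_nested([month, day])
    codes = [_factorize(month), _factorize(day)]
    order, starts = _sorted_structure(codes)
    ys = y[order]
    Xs = X[order]
    Z = np.column_stack([Xs, ys])
    day_starts = starts[1]
    n_day = np.diff(np.append(day_starts, n)).astype(float)
    month_starts_day = np.searchsorted(day_starts, starts[0])
    reml = method.upper() == "REML"
    dof = n - p if reml else n

    def pieces(z):
        gam_d, gam_m = np.exp(np.clip(z, _ZMIN, _ZMAX))
        M, logdetV, *rest = _two_level_pieces(
            Z, day_starts, month_starts_day, n_day, gam_d, gam_m)
        A = M[:p, :p]
        b = M[:p, p]
        cyy = M[p, p]
        beta = np.linalg.solve(A, b)
        rss = max(float(cyy - b @ beta), 1e-300)
        return A, beta, rss, logdetV

    def objective(z):
        A, _, rss, logdetV = pieces(z)
        crit = dof * math.log(rss) + logdetV
        if reml:
            crit += float(np.linalg.slogdet(A)[1])
        return 0.5 * crit

    z0 = np.array([math.log(0.1), math.log(0.1)])
    res = optimize.minimize(objective, z0, method="Nelder-Mead",
                            options=dict(xatol=1e-9, fatol=1e-11,
                                         maxiter=2000, maxfev=4000))
    res = optimize.minimize(objective, res.x, method="Nelder-Mead",
                            options=dict(xatol=1e-10, fatol=1e-12,
                                         maxiter=1000, maxfev=2000))
    zhat = np.clip(res.x, _ZMIN, _ZMAX)
    gam_d, gam_m = np.exp(zhat)
    A, beta, rss, logdetV = pieces(zhat)
    sigma2_resid = rss / dof
    cov_beta = sigma2_resid * np.linalg.inv(A)
    if reml:
        m2ll = ((n - p) * (_LOG2PI + 1.0 + math.log(sigma2_resid))
                + logdetV + float(np.linalg.slogdet(A)[1]))
    else:
        m2ll = n * (_LOG2PI + 1.0 + math.log(sigma2_resid)) + logdetV
    fitted_fixed = X @ beta
    if names is None:
        names = tuple(f"x{j}" for j in range(p))
    fit = MixedModelFit(
        beta=beta,
        se_beta=np.sqrt(np.diag(cov_beta)),
        cov_beta=cov_beta,
        names=tuple(names),
        sigma2_month=float(gam_m * sigma2_resid) if gam_m > 1e-12 else 0.0,
        sigma2_day=float(gam_d * sigma2_resid) if gam_d > 1e-12 else 0.0,
        sigma2_resid=float(sigma2_resid),
        loglik=-0.5 * m2ll,
        method="REML" if reml else "ML",
        n=n,
        var_fixed=float(np.var(fitted_fixed)),
        converged=bool(res.success),
    )
    fit._refit = dict(y=y, X=X, month=month, day=day, names=tuple(names),
                      order=order, starts=starts, zhat=zhat)
    return fit


def predict_random(fit: MixedModelFit) -> np.ndarray:
    """Per-observation BLUPs ``a_month + b_day`` (original row order)."""
    d = fit._refit
    y, X, order = d["y"], d["X"], d["order"]
    starts = d["starts"]
    n, p = X.shape
    gam_d = fit.sigma2_day / fit.sigma2_resid
    gam_m = fit.sigma2_month / fit.sigma2_resid
    r = (y - X @ fit.beta)[order]
    day_starts = starts[1]
    n_day = np.diff(np.append(day_starts, n)).astype(float)
    month_starts_day = np.searchsorted(day_starts, starts[0])
    c_d = gam_d / (1.0 + gam_d * n_day)
    Sr = np.add.reduceat(r, day_starts)                    # per-day sums
    a_m = np.add.reduceat(n_day - c_d * n_day**2, month_starts_day)
    k_m = gam_m / (1.0 + gam_m * a_m)
    ur = np.add.reduceat((1.0 - c_d * n_day) * Sr, month_starts_day)
    # V^-1 r, expanded through both Woodbury corrections
    day_of_obs = np.repeat(np.arange(day_starts.size),
                           np.diff(np.append(day_starts, n)).astype(int))
    month_of_day = np.repeat(
        np.arange(month_starts_day.size),
        np.diff(np.append(month_starts_day, day_starts.size)).astype(int))
    month_of_obs = month_of_day[day_of_obs]
    vinv_r = (r - c_d[day_of_obs] * Sr[day_of_obs]
              - k_m[month_of_obs] * ur[month_of_obs]
              * (1.0 - c_d[day_of_obs] * n_day[day_of_obs]))
    b_day = gam_d * np.add.reduceat(vinv_r, day_starts)
    b_month = gam_m * np.add.reduceat(vinv_r, starts[0])
    pred_sorted = b_day[day_of_obs] + b_month[month_of_obs]
    pred = np.empty(n)
    pred[order] = pred_sorted
    return pred


def fit_mixed_line(y, x, hour_labels, month_labels, day_labels,
                   method: str = "REML") -> MixedModelFit:
    """Below-canopy ~ open-field line with a diurnal harmonic.

    Fixed effects: intercept, open-field temperature, and the first diurnal
    harmonic sin(2*pi*h/24), cos(2*pi*h/24); random intercepts for month and
    day nested in month.
    """
    x = np.asarray(x, dtype=float).ravel()
    h = np.asarray(hour_labels, dtype=float).ravel()
    ang = 2.0 * np.pi * h / 24.0
    X = np.column_stack([np.ones_like(x), x, np.sin(ang), np.cos(ang)])
    return fit_mixed_model(y, X, month_labels, day_labels,
                           names=("intercept", "x", "sin_hour", "cos_hour"),
                           method=method)


def refit_ml(fit: MixedModelFit) -> MixedModelFit:
    if fit.method == "ML":
        return fit
    d = fit._refit
    return fit_mixed_model(d["y"], d["X"], d["month"], d["day"],
                           names=d["names"], method="ML")


def lrt_compare(fit_full: MixedModelFit, fit_null: MixedModelFit):
    """Likelihood-ratio chi-square between nested fixed-effect designs.

    Both models are refit by maximum likelihood if they were estimated by
    REML (fixed-effect likelihoods are not comparable across designs under
    REML).  Returns ``(chi2, df, p)``.
    """
    full = refit_ml(fit_full)
    null = refit_ml(fit_null)
    df = full.p - null.p
    if df < 0:
        raise ValueError("fit_full has fewer fixed parameters than fit_null")
    chi2 = 2.0 * (full.loglik - null.loglik)
    if chi2 < -1e-6:
        raise ValueError(
            "full model has lower likelihood than the null; models are not "
            "nested or the fit did not converge")
    chi2 = max(chi2, 0.0)
    p = 1.0 if df == 0 else float(sps.chi2.sf(chi2, df))
    if df == 0 and chi2 < 1e-8:
        p = 1.0
    return float(chi2), int(df), p


def r2_mixed(fit: MixedModelFit) -> tuple[float, float]:
    """Marginal and conditional coefficients of determination.

    ``R2m`` is the share of total variance explained by fixed effects alone;
    ``R2c`` additionally credits the random intercepts (variance-partition
    form widely used for mixed models).
    """
    denom = (fit.var_fixed + fit.sigma2_month + fit.sigma2_day
             + fit.sigma2_resid)
    if denom <= 0:
        raise ValueError("total variance is zero")
    r2m = fit.var_fixed / denom
    r2c = (fit.var_fixed + fit.sigma2_month + fit.sigma2_day) / denom
    return float(r2m), float(r2c)
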