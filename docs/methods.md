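# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `microbuffer`.

## Data model and QC

A campaign is a tidy stream of records `(timestamp, site, position,
variable, value)` with positions `below_canopy` / `open_field` and
variables `air_T` (°C, 10 cm above ground), `rh` (%), `soil_T` (°C, 10 cm
depth), `soil_m` (m³/m³). Timestamps are local solar time without DST, so
the diurnal harmonic keeps a stable phase; the half-hourly grid is the
native resolution. Each (site, position, variable) series is regularised
onto the common grid (absent slots flagged `gap`) and screened once with a
global mean ± 3 SD rule computed on the full raw record. The screen is
deliberately non-iterative — re-screening flags nothing new — and flagged
values are excluded from every downstream statistic. Aggregation to daily
or ISO-week bins uses only unflagged values; a bin below the completeness
threshold (default 0.9 of its grid slots) reports missing statistics so
daily extremes are not biased by gaps. Seasons are JJA, DJF (December
joined with the following January/February), and the growing season GS =
May 1 – September 30.

## Offset estimation

The temperature offset ΔT (below-canopy minus open-field, negative =
cooler under the canopy) is defined only at slots where both positions
carry unflagged values. Seasonal mean offsets come from an intercept-only
linear mixed model with nested random intercepts for month, day-in-month
and hour-in-day (an hour cell holds the two half-hourly records), fitted by
REML. The likelihood of a purely nested Gaussian model factorises level by
level — children of a node collapse onto their precision-weighted mean with
variance `1/W + σ²_level` — giving an exact O(N) evaluation without
forming covariance matrices; a test verifies it against a direct
multivariate-normal computation. Optimisation is Nelder–Mead on log
variances (clipped at e⁻³⁰, i.e. floored at zero for reporting) with a
polish restart; for balanced designs the solution matches the closed-form
nested-ANOVA moment estimators to ~1e-7 relative, and the tests demand
1e-4. s.e.(μ) is the GLS standard error `(Σ_m 1/V_m)^{-1/2}`, which
honours the nesting. Daily-extreme offsets are **differences of per-day
extremes** (max_below − max_open, likewise minima), not extremes of
differences, and use month-level nesting only since one value per day
remains. Labels must be properly nested; callers compose hour labels as
`date:hour` strings, and a day label reused under two months is rejected.

## Offset response, nonlinearity, decoupling

The offset-response model is `ΔT = β0 + β1·T_out + β2·sin(2πh/24) +
β3·cos(2πh/24) + a_month + b_day + ε`, fitted by REML with the residual
variance and fixed effects profiled out analytically (two nested
rank-one Woodbury updates reduce everything to grouped sums), leaving a
two-dimensional optimisation over log variance ratios. Fixed-effect
estimates agree with an independent mixed-model implementation
(statsmodels MixedLM, used in tests only) to ~1e-3 on small data. The
likelihood-ratio χ² against the intercept-only model refits both models by
maximum likelihood internally (REML likelihoods are not comparable across
fixed-effect designs); estimates are still reported from REML. The
marginal and conditional R² use the variance-partition form: R²m =
var(Xβ)/(var(Xβ)+σ²_month+σ²_day+σ²_e), with the random variances moved
into the numerator for R²c.

Nonlinearity is probed with a penalized cubic B-spline: 10 interior knots
at quantiles of `x`, a **second divided-difference** penalty on the
coefficients (plain second differences would penalise a straight line when
knots are uneven, because a line's B-spline coefficients are linear in the
unevenly spaced Greville abscissae), and λ chosen by GCV on a 53-point log
grid; among GCV ties (relative 1e-7) the largest λ wins, so exactly linear
data collapse onto the line. Reported effective degrees of freedom exclude
the intercept (a linear fit has edf 1, the additive-model convention).
Because the full spline-plus-random-effects model is expensive and rarely
changes the verdict, the pipeline fits the spline to the partial residual
after removing the harmonic fixed effects and the random-intercept BLUPs
from the mixed line — documented as an approximation to a full additive
mixed model.

Hourly decoupling: per hour of day, OLS of T_in on T_out across the season
(slope = strength of coupling). An hour is decoupled when the slope is
below 0.8 **and** its 95% CI upper bound is below 1; both thresholds are
configurable because the qualitative day/night pattern, not a canonical
cutoff, is what the classification encodes. Hours with fewer than 30 pairs
report missing rather than failing.

## Buffering capacity

The growing-season daily means define the coupling line `y = α + βx`. Its
discrepancy from the identity line, `f(x) = α + (β−1)x`, crosses zero at
`x* = α/(1−β)`; the buffering capacity is the closed-form integral of
`max(f, 0)` (canopy-warmer side) and `max(−f, 0)` (canopy-cooler side)
over the observed open-field range, in °C. The closed form is validated
against a trapezoid oracle on 1000 random configurations at 1e-6. For
β = 1 the lines are parallel and the whole range contributes `|α|·(x_max −
x_min)` to one side. Integration bounds default to the observed range of
the seasonal daily means. When published figures print a crossing point
that disagrees with the rounded coefficients, the computed x* is
authoritative; `x_star_override` exists for reproduction runs (it moves
the split, not the integrand). Published areas computed from rounded
coefficients can likewise disagree with the closed form on those same
coefficients — one widely circulated warm-range value differs by ~30% —
so the package always reports its own integral. Site contrast uses an
ANCOVA on pooled daily means, `T_in ~ T_out × site`, whose interaction
term tests for unequal slopes.

## Soil, snow, phenology

A day is a snow candidate when its mean soil temperature lies in
[−0.5, 1.5] °C **and** its diurnal amplitude is below 1.0 °C (the
zero-curtain signature of an insulating snowpack); runs of ≥ 3 consecutive
calendar days become snow periods. Loosening either threshold can only
grow the candidate set, so detection is monotone in the thresholds.
Thermal amplitude is daily max − min with window summaries. NDVI phenology
smooths the 23 yearly 16-day composites with a Savitzky–Golay filter
(window 5, order 2), sets the baseline to the mean of winter composites
and the threshold to baseline + 0.5 × amplitude (the fraction is a
configuration knob, since threshold conventions vary between products),
and locates SOS/EOS as the first upward and last downward crossings by
linear interpolation between composite dates. LOS = EOS − SOS holds as an
identity for every output; published phenology tables sometimes report a
LOS from a different smoothing that violates it, which this package does
not attempt to reproduce.

## The synthetic generator

The generator emulates the paired-station data structure so every stage is
testable without restricted field data. Open-field air temperature is an
annual cosine (mean, half-amplitude, peak day-of-year) plus a diurnal
cosine peaking at 14:00 solar time whose half-amplitude interpolates
sinusoidally between summer and winter values, plus stationary AR(1) noise
(ρ = 0.95 per half-hour) and a day-scale synoptic AR(1) term (sd 2.0 °C,
day-to-day ρ = 0.6) shared by the whole day — the synoptic term is what
spreads daily means over a realistically wide range. Below-canopy air is
`α + β·p(h)·T_out` with a 24-value hourly profile `p` (night values above
1, a hard late-morning dip on the south aspect), plus nested
month/day/hour random intercepts (defaults 0.05/0.5/0.2 °C — most
month-scale structure is already deterministic, so the residual month sd
is small) and independent AR(1) noise at half the open-field sd (canopy
smoothing). Soil temperature is an exponentially smoothed (6 h time
constant), amplitude-damped transform of the position's air temperature,
clamped to ±0.3 °C inside configured snow windows (the northwest site
carries one long winter window per position; the south site alternating
5-day March blocks). Soil moisture follows shared Poisson rain events with
exponential depths, reduced below canopy by the interception fraction,
with exponential dry-down between events (hence non-increasing there).
Logger gaps are Bernoulli per slot and position; sensor spikes of
±U(8, 15)·SD are injected into the temperature channels only (so bounded
variables keep their physical ranges) and logged for recall tests.

**Ground truth is computed, never re-simulated.** Seasonal mean offsets
are means of the deterministic offset over the season's grid slots (all
noise terms are zero-mean). The daily-mean coupling line is the
*population* regression: deterministic day-to-day covariances plus exact
closed-form noise moments — the same AR(1) and synoptic noise enters both
axes, so the population slope differs from the slope of the deterministic
curves, and both the truth and the calibration account for it.
Daily-extreme offsets add a noise-bias correction (the expected maximum of
a noisy day exceeds the deterministic maximum, differently for the two
positions) evaluated by a fixed-seed Monte Carlo over the noise processes
only, jointly for the two positions and with independent draws per day;
it is deterministic given the configuration and stable to ~0.015 °C.

The default two-site campaign is calibrated once (deterministically,
cached) so its implied truths equal the study-scale values: growing-season
mean offsets −2.41 °C (S) and −1.01 °C (NW), daily-mean coupling slopes
0.60 (S) and 0.76 (NW), and a summer daily-maximum offset of −8.63 °C
(S). The coupling slope is linear in β and the seasonal mean linear in α,
so both are solved directly; the daily-maximum target is met by warping
the sub-unity (daytime) part of the hourly profile with a 1-D root find on
the warp exponent, leaving night-time values fixed so the canopy maximum
stays anchored to the warm hours.

**What the generator does not emulate**, hence what passing tests do not
show about real data: radiative and wind-driven energy balance; a leafless
deciduous canopy in winter (the coupling is constant year-round, so the
generated winter offsets are positive and larger than field campaigns
typically report); observed canopy soils that can be *warmer* than
open-field soils through litter/radiation effects (generated soil follows
air temperature, so canopy soils are cooler in summer); instrument drift;
and spatial within-site heterogeneity.

## Problem sizes and reproducibility

One synthetic year is ~20,300 half-hourly slots per series (317,000
records for two sites); generation takes well under a second and the full
pipeline a few tens of seconds, dominated by the REML fits. The acceptance
script's recovery tier uses twenty one-year campaigns — enough for the
18-of-20 two-standard-error criterion to be meaningful while keeping the
whole run in minutes on one CPU. Every random draw descends from a single
integer seed; identical configuration plus seed reproduces records,
reports and JSON output byte for byte (reports carry no wall-clock
timestamps).

## Known limitations

* The REML optimiser is derivative-free; with near-zero variance
  components it converges to the clipped boundary rather than an exact
  zero (values below 1e-8 of the total variance are reported as 0).
* The GAMM-style spline probe conditions on BLUPs from the linear mixed
  fit instead of refitting spline and random effects jointly; its edf is
  indicative, not an exact test statistic.
* Hourly coupling CIs use the normal approximation (n ≥ 30 per hour).
* DJF estimates need a campaign that spans the year boundary; single-summer
  campaigns must restrict `seasons`.
* The daily-extreme ground truth depends on a Monte Carlo constant
  (fixed internal seed, 400 replicates per day); its residual error
  (~0.015 °C) is negligible against the estimator's standard errors but
  is not exactly zero.
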