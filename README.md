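# microbuffer

Forest canopies buffer the microclimate beneath them: on warm days the
near-ground air below the canopy stays cooler than the adjacent open field,
and on cold nights it stays warmer. `microbuffer` quantifies this effect for
paired-station campaigns — a below-canopy logger and an open-field reference
recording half-hourly air temperature, relative humidity, soil temperature
and soil moisture — of the kind used to characterise treeline microclimate
on contrasting aspects. It is aimed at forest ecologists and
environmental biostatisticians who want the full analysis chain (QC →
offsets → coupling → buffering capacity → soil/snow/phenology summaries) as
tested, reusable code rather than a one-off script.

## The statistics at the core

**Temperature offset.** ΔT = T_below-canopy − T_open-field at matched time
stamps (negative = cooler under the canopy). Seasonal means are estimated
with an intercept-only linear mixed model with nested random intercepts,

ΔT_mdht = μ + a_m + b_md + c_mdh + ε, a ~ N(0, σ²_month),
b ~ N(0, σ²_day), c ~ N(0, σ²_hour),

fitted by REML with an exact O(N) likelihood that exploits the purely
nested covariance structure. μ is the seasonal offset and s.e.(μ) honours
the month/day/hour dependence. Daily-extreme offsets (difference of per-day
maxima or minima) use the same estimator with month nesting only.

**Offset response and decoupling.** ΔT is regressed on open-field
temperature with a first diurnal harmonic, sin(2πh/24) and cos(2πh/24), as
fixed effects and month/day random intercepts; a χ² likelihood-ratio test
against the intercept-only model, marginal/conditional R², and a
GCV-penalized cubic spline probe for nonlinearity accompany the fit.
Per-hour OLS slopes of T_in on T_out classify each hour of day as coupled
or decoupled (default rule: decoupled when the slope is below 0.8 and its
95% CI stays below 1).

**Buffering capacity.** The growing-season daily means give a coupling line
y = α + βx. Its crossing with the 1:1 line is x* = α/(1−β), and the
buffering capacity on each side is the closed-form thermal sum

B = ∫ |α + (β−1)x| dx

integrated from the observed range bound to the crossing: the canopy-warmer
side (x < x* for β < 1) and the canopy-cooler side (x > x*), in °C.

A seeded synthetic-campaign generator with known ground truth (annual +
diurnal sinusoids, AR(1) and day-scale synoptic noise, hour-varying
coupling, snow windows that clamp soil temperature near 0 °C, interception
-driven soil-moisture contrasts, logger gaps and sensor spikes) makes every
stage testable end to end.

## Worked example

```python
from microbuffer.pipeline import RunConfig, run_pipeline, report_summary

report = run_pipeline(RunConfig(seed=1))
print(report_summary(report))
```

prints (abridged):

```
site NW: coupling y = 1.49 + 0.77 x over [3.35, 18.09]  x* = 6.46
  buffering: canopy-warmer 1.1 degC, canopy-cooler 15.6 degC
  JJA mean offset: -1.43 +/- 0.11 degC (n=5502)
  DJF mean offset: +1.56 +/- 0.10 degC (n=4036)
   GS mean offset: -1.07 +/- 0.19 degC (n=9639)
site S: coupling y = 3.53 + 0.59 x over [8.85, 20.51]  x* = 8.52
  buffering: canopy-warmer 0.0 degC, canopy-cooler 29.8 degC
  JJA mean offset: -3.07 +/- 0.14 degC (n=5509)
  DJF mean offset: +2.80 +/- 0.11 degC (n=4064)
   GS mean offset: -2.51 +/- 0.29 degC (n=9655)
slope difference S - NW: -0.184 (p = 1.3e-12)
```

Reading this: on the synthetic south-aspect site the understory averaged
2.51 ± 0.29 °C cooler than the open field over the growing season (the
generator's configured truth is −2.41 °C), the coupling slope 0.59 means a
1 °C open-field warming moves the understory only ~0.6 °C, and the thermal
sum of that shortfall beyond the crossing point (canopy-cooler side) is
29.8 °C over the observed range. The interaction test confirms the two
aspects buffer differently. The same pipeline runs on real record CSVs
(`RunConfig(records_csv=...)`) with the dialect
`timestamp,site,position,variable,value`.

A command-line interface mirrors the library:

```
microbuffer simulate --seed 1 --out sim/
microbuffer run --records sim/records.csv --out report/
microbuffer phenology --ndvi ndvi.csv --out phen.json
```

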