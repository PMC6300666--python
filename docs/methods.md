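# Methods

This document defines the models, conventions and numerical choices used by
`scdshift`, in enough detail to reproduce any number the package emits.

## 1. Curve decomposition

A CO2 record `(t_i, c_i)` (t in days since the first record) is modelled as

```
c(t) = P(t) + H(t) + r(t)
P(t) = a0 + a1·t + a2·t²                      (quadratic trend polynomial)
H(t) = Σ_{k=1..4} [ b_k cos(2πkt/T) + c_k sin(2πkt/T) ]
```

fitted jointly by ordinary least squares on the retained records. The
polynomial is fitted in a centred and scaled time variable for conditioning
and converted back to the days-since-start basis. The number of harmonics is
4. The period `T` is 365.25 days for real (gregorian-calendar) records and
365.0 days for the synthetic world, which uses a 365-day no-leap calendar
throughout (February 29 records of real data are dropped at read time; the
true ordinal-day spacing of the remaining records is preserved). A fit
requires at least 3 full years of span.

The residuals `r(t)` are smoothed on a daily grid by two gap-aware Gaussian
filters specified by full width at half maximum (FWHM):

- short filter: FWHM = 45.66 days (= 1.5 × 365.25/12), passing intraseasonal
  structure,
- long filter: FWHM = 390 days, isolating interannual trend variation.

`σ = FWHM / (2√(2 ln 2))`. Smoothing is normalized convolution
(`num = conv(value·mask, kernel)`, `den = conv(mask, kernel)`, kernel
truncated at ±4σ) so data gaps neither bias the estimate nor shrink it
toward zero; a day with no observation within ±3σ is marked missing.

The decomposition then defines

```
D(t)     = H(t) + [S(t) − L(t)]     (detrended seasonal curve)
trend(t) = P(t) + L(t)
```

with `S` and `L` the short- and long-filtered residuals. The identity
`trend + D + (r − S) = c` holds to 1e-9 ppm and is asserted in the tests.

**Outlier rejection.** Before the final fit, daily records are screened
iteratively (at most 5 passes): fit, compute the residual standard
deviation, flag records more than 5 SD from the fit, refit. Weekly
(flask/GLOBALVIEW-style) records skip rejection. A floor on the SD guards
numerically exact fits from flagging roundoff noise.

## 2. Summer CO2 drawdown (SCD) and phenology

The SCD of year `y` is the mean of `D(t)` over July 1–7 (day-of-year
182–188) minus its mean over August 25–31 (DOY 237–243). Positive SCD means
drawdown. "First week of July / last week of August" have no universal DOY
convention; these fixed windows are this package's definition, stable across
years because of the no-leap handling. Two alternative definitions are
provided: windows anchored on the climatological phenology dates and on each
year's own dates.

Phenology of `D(t)`:

- **Downward zero crossing**: linear interpolation between the bracketing
  days, searched in DOY 100–300; if several crossings exist the one nearest
  DOY 178 is used.
- **Trough**: minimum of `D` in DOY 150–300, refined by a quadratic fit
  through the minimum and its two neighbours.

Date trends are ordinary least-squares slopes on year (≥ 5 years required);
an *advance* is the negative of the slope.

## 3. Regional aggregation

Regional series are cos(latitude)-weighted means over vegetated pixels
north of 50° N. Vegetated means climatological (multi-year mean) annual NDVI
strictly greater than 0.1. Summer values are July–August means
(precipitation: sums). The footprint weighting alternative multiplies the
station sensitivity field by cos(latitude) with no cutoff.

Extreme warm days in a year are July–August days strictly above the
per-pixel 90th percentile (linear-interpolation quantile) of all July–August
days pooled over a base period of at least 5 years. Daily-temperature
variability is the sample SD (ddof = 1) of a year's July–August daily
temperatures, requiring at least 50 of the 62 days.

## 4. Statistics

All period statistics are computed on series **linearly detrended within the
period**. The central quantity is the partial correlation `R_SCD-T` between
SCD and regional summer temperature given the controls (default: summer
precipitation and cloud), computed by residualizing both series on the
controls; the p-value uses `t = r·√((n−2−k)/(1−r²))` with `k` controls,
two-sided. The sensitivity `γ_SCD-T` is the temperature coefficient of an
OLS regression of SCD on temperature and the controls (ppm per °C).

**Subsample distributions.** Sampling uncertainty of a period's `r` is the
distribution of the statistic over subsamples of `m` of the `n` years
(default `m = n − 3`). All `C(n, m)` subsets are enumerated when there are
at most 5000 (e.g. `C(17, 14) = 680`); otherwise 1000 seeded random subsets
are drawn. Periods are compared by a Welch two-sample t-test on the draws;
γ values by a z-test on the coefficient difference using the regression
standard errors.

**Moving window.** `R_SCD-T` is recomputed in 15-year sliding windows, each
window detrended independently, and the OLS slope of `r` on window-centre
year summarizes its evolution. Consecutive windows share 14 of 15 years, so
the windowed correlations are strongly serially dependent and a naive OLS
p-value on that slope is badly anticonservative (≈ 75 % false positives
under a stationary coupling in Monte-Carlo checks; an AR(1)
effective-sample-size correction is still insufficient because the
dependence extends to lag 14). The slope is therefore tested by
**permutation**: the (SCD, T, controls) year-tuples are jointly shuffled 199
times after full-record detrending — under a stationary coupling the years
are then exchangeable — and the p-value is the fraction of permuted slopes
at least as extreme as the observed one (+1 correction). Because the
diagnostic exists to detect an *emerging negative* temperature control, the
default alternative is one-sided ("less", declining r); "greater" and
"two-sided" are available. The permutation test is exactly calibrated under
the null (verified by Monte-Carlo in the test suite).

**Lagged correlations** shift the predictor back by 1–2 years (controls stay
contemporaneous); **pixelwise maps** apply the detrended partial correlation
at every grid pixel and report r, p and significance masks at P < 0.05 and
P < 0.1.

## 5. Synthetic generator

The generator produces a world with *known* structure so every stage of the
pipeline can be tested against truth. All randomness derives from one root
seed via independent named streams (`np.random.default_rng([seed, stream])`),
so adding a field never perturbs another field's draws.

Default configuration (`TruthParams`): 1979–2012, 365-day years; CO2 =
345 ppm + (1.7 ppm yr⁻¹ + quadratic) trend + fixed 4-harmonic seasonal cycle
(calibrated once, at design time, to emulate a Barrow-like cycle:
climatological zero crossing ≈ DOY 177, trough ≈ DOY 235, SCD ≈ 10.6 ppm) −
an imposed drawdown anomaly + AR(1) noise (ρ = 0.65, marginal SD 1.5 ppm) +
5 % gaps + rare large spikes (rate 0.003, 5–20 SD).

The imposed per-year drawdown anomaly is `d_y = coupling(period)·T_y + ε_y`
with `coupling = 0` before the 1996 break year and `−2 ppm °C⁻¹` from it on,
`T_y` the regional temperature anomaly mode (SD 1 °C) and ε white noise
(SD 0.8 ppm). It enters the series through a smooth ramp that is exactly 0
over the July window and exactly 1 over the August window, so the
fixed-window SCD of the noise-free series equals the imposed anomaly
*exactly* — the truth record is an oracle by construction, not by
calibration.

Climate fields (default 20 × 40 grid, 50–80° N) share the same regional
temperature mode with loading 1, plus a warming trend and spatially
correlated pixel noise; daily temperatures add a seasonal cycle peaking at
DOY 196 and day-to-day noise. NDVI couples to summer temperature with a
period-dependent β and optional extreme-day heat penalty; heterotrophic
respiration follows a Q10 law; the station footprint is a smooth bump at
(71° N, 203° E); sea-ice extent declines linearly with noise.

**Scope.** The generator emulates the *statistical structure* relevant to
the analysis (a coupling that switches at a break year, coherent regional
modes, realistic noise, gaps and spikes). It does not emulate atmospheric
transport, synoptic variability, non-CO2 tracers, or spatial propagation of
the drawdown signal; the CO2 record and climate fields are linked only
through the shared regional temperature mode.

## 6. Known numerical properties and limitations

- **γ attenuation.** The 45.66-day FWHM band-pass that defines `D(t)`
  attenuates the ~50-day drawdown ramp, so the pipeline recovers
  γ ≈ 0.5–0.8 of an injected coupling (mean ≈ −1.4 for −2 injected at
  default noise). Correlations are scale-free and unaffected; conclusions
  about the sign, significance and decadal change of the temperature control
  are insensitive to the attenuation, but recovered γ magnitudes from any
  band-pass-based SCD should be read as lower bounds.
- Quantile method for extreme thresholds is linear interpolation (numpy
  default); other methods move the threshold by O(0.1 °C) on 62-day pools.
- The permutation p-value has resolution 1/200 at the default 199
  permutations; raise `n_perm` for finer p-values.
- Fixed windows (DOY 182–188 / 237–243) versus calendar windows differ by at
  most one day in leap years of real records; the no-leap convention removes
  the ambiguity for synthetic data.
- Edge years of a record lack full filter support; decomposition marks them
  and SCD is only computed for fully covered years.
- The subsample Welch comparison treats draws as independent, which
  overstates the effective sample size of overlapping subsets; its p-value
  is a descriptive index of separation, consistent across periods, not an
  exact test.
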