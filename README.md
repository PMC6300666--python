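# scdshift

Tools for quantifying the **summer CO2 drawdown (SCD)** of a high-northern
CO2 record and for testing whether its interannual control by summer
temperature changed between decades.

At high-latitude stations the CO2 seasonal cycle plunges through the growing
season as the land biosphere takes up carbon. The SCD — the mean of the
detrended seasonal curve over the first week of July minus its mean over the
last week of August — is a simple, robust index of that summer uptake. The
scientific question this package addresses is whether the year-to-year
relationship between SCD and regional summer temperature is stable, or
whether a warming-driven shift (earlier phenology, heat stress, rising
respiration) has flipped warm summers from being good for uptake to bad for
it. The package provides every stage of that analysis:

- **`scdshift.curvefit`** — Thoning-style decomposition of a daily or weekly
  CO2 record: quadratic polynomial plus four seasonal harmonics fitted by
  least squares, residuals split by gap-aware Gaussian FWHM filters (45.66
  and 390 days) into short-term seasonal structure and long-term trend
  variation, with iterative 5-SD outlier rejection. The detrended seasonal
  curve is D(t) = harmonics + band-passed residuals.
- **`scdshift.scd`** — per-year SCD under three window definitions
  (fixed calendar windows, climatological phenology dates, annual phenology
  dates), plus zero-crossing and trough dates of D(t) and their trends.
- **`scdshift.spatial`** — cos(latitude)-weighted and station-footprint-
  weighted regional means of gridded summer fields, vegetated-pixel masking
  by climatological NDVI, extreme-warm-day counts against a base-period
  90th percentile, and daily-temperature variability.
- **`scdshift.stats`** — detrended partial correlations with controls
  (R_SCD-T), subsample distributions over all C(n, m) year subsets,
  regression sensitivities (γ_SCD-T, ppm per °C), Welch/z period
  comparisons, 15-year moving-window correlations with a permutation test
  for a declining r, lagged correlations, and pixelwise correlation maps.
- **`scdshift.synthetic`** — a fully seeded synthetic world (CO2 record with
  known injected temperature–drawdown coupling that switches at a break
  year, coherent regional climate fields, NDVI, heterotrophic respiration,
  station footprint, sea-ice series) whose written truth record makes every
  pipeline stage testable against known answers.
- **`scdshift.cli` / `scdshift.pipeline`** — a `scdshift` command with
  `simulate`, `fitcurve`, `scd`, `aggregate` and `run` subcommands, driven
  by a YAML `RunConfig`; one root seed controls all randomness.

## Worked example

Simulate a 34-year (1979–2012) synthetic world whose temperature–drawdown
coupling is 0 before 1996 and −2 ppm °C⁻¹ from 1996 on, decompose the CO2
record, and measure the SCD:

```python
import numpy as np
from scdshift import TruthParams, simulate_world, decompose, scd_series

params = TruthParams(seed=1)
world = simulate_world(params)
decomp = decompose(world["co2"])
print(f"outliers removed: {decomp.n_outliers_removed}")

records = scd_series(decomp, "fixed-window", params.years)
scd = np.array([r.scd for r in records])
print(f"mean SCD: {scd.mean():.2f} ppm  (range {scd.min():.2f} to {scd.max():.2f})")
```

```
outliers removed: 45
mean SCD: 10.77 ppm  (range 8.19 to 13.52)
```

Run the full analysis — detrended partial correlation of SCD with regional
summer temperature, controlling for precipitation and cloud, in the two
periods 1979–1995 and 1996–2012:

```python
from scdshift.pipeline import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(seed=1), write=False)
for period in ("early", "late"):
    p = summary["periods"][period]
    print(f"{period}: r_SCD-T = {p['r_scd_t']:+.2f} (P = {p['p']:.3f}), "
          f"gamma = {p['gamma_scd_t']:+.2f} ppm/degC")
mw = summary["moving_window"]
print(f"moving-window trend in r: {mw['r_trend_per_year']:+.3f} per year "
      f"(P = {mw['r_trend_p']:.3f})")
```

```
early: r_SCD-T = -0.10 (P = 0.714), gamma = -0.10 ppm/degC
late: r_SCD-T = -0.82 (P = 0.000), gamma = -1.11 ppm/degC
moving-window trend in r: -0.054 per year (P = 0.010)
```

The pipeline recovers the imposed structure: no temperature control in the
early period, a strongly negative and significant control in the late
period, and a significantly declining moving-window correlation. (The
recovered γ magnitude is attenuated relative to the injected −2 ppm °C⁻¹ by
the band-pass that defines D(t); see `docs/methods.md`.)

The same analysis from the command line:

```bash
scdshift run --seed 1 --outdir out/
# writes scd.csv, regional_series.csv, decomposition.csv, fit.json,
# correlations.csv, truth.json, summary.json
```

## Documentation

See `docs/methods.md` for the decomposition model, the exact SCD and
phenology definitions, the statistical machinery (including why the
moving-window trend uses a permutation test), the design of the synthetic
generator, and known limitations.
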