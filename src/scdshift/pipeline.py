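"""End-to-end orchestration: simulate -> decompose -> SCD -> aggregate -> correlate.

A :class:`RunConfig` (YAML-loadable) names the analysis periods, the SCD
definition, the regional weighting and the control variables; one root seed
drives every random component.  :func:`run_pipeline` writes the per-stage
tables (CSV) plus a machine-readable ``summary.json`` whose headline entries
are the partial correlation R_SCD-T and sensitivity gamma_SCD-T for each
period and the significance of their difference.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curvefit import decompose, read_co2
from .scd import records_to_frame, scd_series
from .spatial import regional_series, vegetated_mask
from .stats import (compare_periods, detrend, lagged_correlation,
                    moving_window_correlation, partial_correlation,
                    sensitivity_slope, subsample_partial_correlation)
from .synthetic import TruthParams, simulate_world


@dataclass
class RunConfig:
    early: tuple = (1979, 1995)
    late: tuple = (1996, 2012)
    scd_method: str = "fixed-window"
    weighting: str = "coslat-north50"
    controls: tuple = ("precip", "cloud")
    seed: int = 0
    n_draws: int = 1000
    subsample_m: int | None = None          # default: period length - 3
    moving_window: int = 15
    co2_path: str | None = None             # analyze a real record instead
    co2_dialect: str = "csv"
    sim: dict = dc_field(default_factory=dict)  # TruthParams overrides
    outdir: str = "scdshift_out"

    def __post_init__(self) -> None:
        e0, e1 = self.early
        l0, l1 = self.late
        if not (e0 <= e1 and l0 <= l1):
            raise ValueError("malformed period bounds")
        if max(e0, l0) <= min(e1, l1):
            raise ValueError("analysis periods overlap")
        for lo, hi in (self.early, self.late):
            if hi - lo + 1 < 8:
                raise ValueError("each analysis period needs at least 8 years")
        if self.co2_path is not None and not Path(self.co2_path).exists():
            raise ValueError(f"CO2 input {self.co2_path} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("early", "late", "controls"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def period_years(self, which: str) -> np.ndarray:
        lo, hi = self.early if which == "early" else self.late
        return np.arange(lo, hi + 1)


def _subset(df: pd.DataFrame, years: np.ndarray, col: str) -> np.ndarray:
    sub = df[df["year"].isin(years)].sort_values("year")
    if len(sub) != len(years):
        missing = sorted(set(years) - set(sub["year"]))
        raise ValueError(f"years missing from {col} series: {missing}")
    return sub[col].to_numpy()


def _period_stats(cfg: RunConfig, which: str, scd_df: pd.DataFrame,
                  series: dict) -> dict:
    years = cfg.period_years(which)
    y = detrend(_subset(scd_df, years, "scd_ppm"), years)
    t = detrend(_subset(series["T"], years, "value"), years)
    ctrl = [detrend(_subset(series[c], years, "value"), years)
            for c in cfg.controls if c != "T"]
    m = cfg.subsample_m or (len(years) - 3)
    pc = partial_correlation(y, t, ctrl, y_name="SCD", x_name="T",
                             control_names=tuple(cfg.controls))
    dist = subsample_partial_correlation(y, t, ctrl, m=m, n_draws=cfg.n_draws,
                                         seed=cfg.seed)
    slope = sensitivity_slope(y, [t] + ctrl,
                              predictor_names=("T",) + tuple(cfg.controls))
    return {"years": years, "pc": pc, "dist": dist, "slope": slope}


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Run the full analysis and return (and optionally write) the summary."""
    outdir = Path(config.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)

    sim_kwargs = dict(config.sim)
    sim_kwargs.setdefault("seed", config.seed)
    params = TruthParams(**sim_kwargs)
    world = simulate_world(params)

    if config.co2_path is not None:
        co2 = read_co2(config.co2_path, config.co2_dialect)
        truth = None
    else:
        co2, truth = world["co2"], world["truth"]

    decomp = decompose(co2)
    all_years = np.concatenate([config.period_years("early"),
                                config.period_years("late")])
    all_years = all_years[np.isin(all_years, decomp.years)]
    records = scd_series(decomp, method=config.scd_method, years=all_years)
    scd_df = records_to_frame(records)

    mask = vegetated_mask(world["ndvi"].mean("year"))
    fp = world["footprint"] if config.weighting == "footprint" else None
    climate = world["climate"]
    series = {
        "T": regional_series(climate["tas"], all_years, mask, config.weighting,
                             fp, variable="T"),
        "precip": regional_series(climate["pr"], all_years, mask, config.weighting,
                                  fp, how="sum", variable="precip"),
        "cloud": regional_series(climate["cloud"], all_years, mask,
                                 config.weighting, fp, variable="cloud"),
    }
    if "sie" in config.controls:
        series["sie"] = pd.DataFrame({"year": params.years, "variable": "sie",
                                      "weighting": "scalar",
                                      "value": world["sie"]})

    per = {w: _period_stats(config, w, scd_df, series) for w in ("early", "late")}
    p_r = compare_periods(per["early"]["dist"], per["late"]["dist"])
    p_gamma = compare_periods(per["early"]["slope"], per["late"]["slope"])

    # moving-window and lagged robustness over the full span
    y_full = _subset(scd_df, all_years, "scd_ppm")
    t_full = _subset(series["T"], all_years, "value")
    ctrl_full = [_subset(series[c], all_years, "value")
                 for c in config.controls if c != "T"]
    mw_results, mw_slope, mw_p = moving_window_correlation(
        y_full, t_full, ctrl_full, years=all_years, window=config.moving_window)
    lags = {lag: lagged_correlation(y_full, t_full, ctrl_full, lag=lag)
            for lag in (1, 2)}

    summary = {
        "version": __version__,
        "seed": config.seed,
        "scd_method": config.scd_method,
        "weighting": config.weighting,
        "controls": list(config.controls),
        "periods": {
            w: {
                "years": [int(per[w]["years"][0]), int(per[w]["years"][-1])],
                "r_scd_t": per[w]["pc"].r,
                "p": per[w]["pc"].p,
                "n": per[w]["pc"].n,
                "subsample_mean_r": per[w]["dist"].mean,
                "subsample_sd_r": per[w]["dist"].sd,
                "subsample_m": per[w]["dist"].m,
                "gamma_scd_t": per[w]["slope"].gamma,
                "gamma_se": per[w]["slope"].se,
                "gamma_p": per[w]["slope"].p,
            } for w in ("early", "late")
        },
        "comparison": {"p_r": p_r, "p_gamma": p_gamma},
        "moving_window": {"window": config.moving_window,
                          "n_windows": len(mw_results),
                          "r_trend_per_year": mw_slope, "r_trend_p": mw_p},
        "lagged": {f"lag{lag}": {"r": res.r, "p": res.p}
                   for lag, res in lags.items()},
        "n_outliers_removed": decomp.n_outliers_removed,
    }

    if write:
        scd_df.to_csv(outdir / "scd.csv", index=False)
        pd.concat(series.values()).to_csv(outdir / "regional_series.csv", index=False)
        decomp.write_csv(outdir / "decomposition.csv")
        decomp.write_fit_json(outdir / "fit.json")
        rows = []
        for w in ("early", "late"):
            pc = per[w]["pc"]
            rows.append({"analysis": "r_scd_t", "period": w, "r": pc.r, "p": pc.p,
                         "n": pc.n, "controls": "+".join(config.controls),
                         "seed": config.seed})
        pd.DataFrame(rows).to_csv(outdir / "correlations.csv", index=False)
        if truth is not None:
            truth.write_json(outdir / "truth.json")
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True))
    return summary


def headline_recovery(seed: int, config: RunConfig | None = None,
                      **sim_overrides) -> dict:
    """Minimal simulate->decompose->SCD->correlate pass for one seed.

    Computes only the headline quantities (per-period R_SCD-T with controls,
    the gamma_SCD-T slopes, and the moving-window trend of r), skipping the
    subsample distributions and vegetation fields.  Used for Monte-Carlo
    checks of the pipeline's structural recovery.
    """
    from .spatial import regional_mean, summer_mean
    from .synthetic import generate_climate_fields, generate_co2_series

    cfg = config or RunConfig()
    params = TruthParams(**{"seed": seed, **sim_overrides})
    co2, truth = generate_co2_series(params)
    climate = generate_climate_fields(params)
    decomp = decompose(co2)
    years = np.concatenate([cfg.period_years("early"), cfg.period_years("late")])
    years = years[np.isin(years, decomp.years)]
    scd_df = records_to_frame(scd_series(decomp, cfg.scd_method, years))

    def reg(name, how="mean"):
        return np.array([regional_mean(summer_mean(climate[name], int(y), how))
                         for y in years])

    t_ser, p_ser, c_ser = reg("tas"), reg("pr", "sum"), reg("cloud")
    scd_vals = _subset(scd_df, years, "scd_ppm")
    out = {}
    for which in ("early", "late"):
        yy = cfg.period_years(which)
        sel = np.isin(years, yy)
        y = detrend(scd_vals[sel], years[sel])
        t = detrend(t_ser[sel], years[sel])
        ctrl = [detrend(p_ser[sel], years[sel]), detrend(c_ser[sel], years[sel])]
        pc = partial_correlation(y, t, ctrl)
        gam = sensitivity_slope(y, [t] + ctrl)
        out[which] = {"r": pc.r, "p": pc.p, "gamma": gam.gamma}
    _, mw_slope, mw_p = moving_window_correlation(
        scd_vals, t_ser, [p_ser, c_ser], years=years, window=cfg.moving_window)
    out["moving_window"] = {"slope": mw_slope, "p": mw_p}
    out["truth_coupling"] = {"early": float(truth.coupling[0]),
                             "late": float(truth.coupling[-1])}
    return out


def config_to_yaml(config: RunConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["early"], d["late"] = list(d["early"]), list(d["late"])
    d["controls"] = list(d["controls"])
    Path(path).write_text(yaml.safe_dump(d))
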