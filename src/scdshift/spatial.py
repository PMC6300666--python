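"""Regional aggregation of gridded fields.

Turns gridded climate / vegetation fields into the per-year regional scalars
the statistics consume: cos(lat)-weighted means over vegetated land north of
50N, footprint(sensitivity)-weighted means, July-August summer composites,
extreme-warm-day counts against a base-period percentile threshold, and the
within-summer daily-temperature variability diagnostic.

Gridded data are xarray DataArrays with ``lat`` / ``lon`` coordinates (and
``year``, ``month`` or ``doy`` as applicable) and a ``units`` attribute.
All inputs to a given operation must share the same grid; mismatches raise
rather than being silently interpolated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats as sps

from .timeaxis import AUG31, JUL1

SUMMER_MONTHS = (7, 8)
N_SUMMER_DAYS = AUG31 - JUL1 + 1  # 62


def _check_grid(a: xr.DataArray, b: xr.DataArray) -> None:
    if not (np.array_equal(a["lat"].values, b["lat"].values)
            and np.array_equal(a["lon"].values, b["lon"].values)):
        raise ValueError("grids do not match (regridding is not supported)")


def vegetated_mask(ndvi_climatology: xr.DataArray, threshold: float = 0.1) -> xr.DataArray:
    """Vegetated land: long-term mean annual NDVI strictly above ``threshold``."""
    if "year" in ndvi_climatology.dims or "time" in ndvi_climatology.dims:
        raise ValueError("pass a time-mean NDVI climatology, not a time series")
    mask = ndvi_climatology > threshold
    mask.attrs["long_name"] = f"mean annual NDVI > {threshold}"
    return mask


def summer_mean(field: xr.DataArray, year: int, how: str = "mean") -> xr.DataArray:
    """July-August composite of a monthly field for one year.

    ``how="mean"`` averages the two months (temperature, cloud, NDVI-like
    fields); ``how="sum"`` totals them (precipitation).
    """
    if how not in ("mean", "sum"):
        raise ValueError("how must be 'mean' or 'sum'")
    try:
        sub = field.sel(year=year, month=list(SUMMER_MONTHS))
    except KeyError as exc:
        raise ValueError(f"year {year}: missing July or August") from exc
    if sub["month"].size != 2:
        raise ValueError(f"year {year}: missing July or August")
    out = sub.sum("month") if how == "sum" else sub.mean("month")
    out.attrs.update(field.attrs)
    return out


def regional_mean(grid: xr.DataArray, mask: xr.DataArray | None = None,
                  lat_min: float = 50.0) -> float:
    """cos(lat)-weighted mean over masked pixels with lat >= lat_min."""
    sel = grid["lat"] >= lat_min
    w = np.cos(np.deg2rad(grid["lat"])) * sel
    if mask is not None:
        _check_grid(grid, mask)
        w = w * mask
    w = w.broadcast_like(grid).where(np.isfinite(grid), 0.0)
    total = float(w.sum())
    if total <= 0:
        raise ValueError("no pixels selected for the regional mean")
    return float((grid * w).sum(skipna=True) / total)


def footprint_weighted_mean(grid: xr.DataArray, footprint: xr.DataArray,
                            mask: xr.DataArray | None = None) -> float:
    """Mean weighted by station sensitivity x cos(lat) over masked pixels.

    No sensitivity cutoff is applied: every pixel with positive weight
    contributes.
    """
    _check_grid(grid, footprint)
    if float(footprint.min()) < 0:
        raise ValueError("footprint sensitivities must be non-negative")
    w = footprint * np.cos(np.deg2rad(grid["lat"]))
    if mask is not None:
        _check_grid(grid, mask)
        w = w * mask
    w = w.broadcast_like(grid).where(np.isfinite(grid), 0.0)
    total = float(w.sum())
    if total <= 0:
        raise ValueError("all footprint weights are zero")
    return float((grid * w).sum(skipna=True) / total)


def regional_series(field: xr.DataArray, years, mask: xr.DataArray | None = None,
                    weighting: str = "coslat-north50",
                    footprint: xr.DataArray | None = None,
                    how: str = "mean", variable: str = "") -> pd.DataFrame:
    """Per-year regional scalar series from a monthly (or per-year) field.

    Fields with a ``month`` dimension are summer-composited first; fields
    already per-year (e.g. summer NDVI) are aggregated directly.
    """
    values = []
    for y in years:
        grid = (summer_mean(field, int(y), how=how) if "month" in field.dims
                else field.sel(year=int(y)))
        if weighting == "coslat-north50":
            values.append(regional_mean(grid, mask))
        elif weighting == "footprint":
            if footprint is None:
                raise ValueError("footprint weighting requires a footprint field")
            values.append(footprint_weighted_mean(grid, footprint, mask))
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
    return pd.DataFrame({"year": np.asarray(years, int), "variable": variable,
                         "weighting": weighting, "value": values})


# ---------------------------------------------------------------------------
# daily-temperature diagnostics


def _summer_days(daily_t: xr.DataArray, year: int) -> xr.DataArray:
    return daily_t.sel(year=year, doy=slice(JUL1, AUG31))


def extreme_warm_days(daily_t: xr.DataArray, base_years, eval_year: int,
                      pctl: float = 90.0) -> xr.DataArray:
    """Count of July-August days strictly above the base-period percentile.

    The threshold is the empirical ``pctl``-th percentile (linear
    interpolation between order statistics) of all July-August daily values
    pooled over ``base_years``, computed per pixel.
    """
    base_years = np.asarray(base_years, int)
    if base_years.size < 5:
        raise ValueError("base period must span at least 5 years")
    pool = daily_t.sel(year=base_years, doy=slice(JUL1, AUG31))
    pool = pool.stack(sample=("year", "doy"))
    thresh = pool.quantile(pctl / 100.0, dim="sample", method="linear")
    days = _summer_days(daily_t, eval_year)
    count = (days > thresh).sum("doy")
    count = count.drop_vars("quantile", errors="ignore")
    count.attrs["units"] = "days"
    count.attrs["long_name"] = f"Jul-Aug days above the {pctl:g}th percentile"
    return count


def extreme_warm_days_all_years(daily_t: xr.DataArray, base_years,
                                pctl: float = 90.0) -> xr.DataArray:
    """Extreme-day counts for every year against one base-period threshold."""
    years = daily_t["year"].values
    counts = [extreme_warm_days(daily_t, base_years, int(y), pctl) for y in years]
    out = xr.concat(counts, dim="year")
    out = out.assign_coords(year=years)
    return out


def temp_variability(daily_t: xr.DataArray, year: int,
                     min_days: int = 50) -> xr.DataArray:
    """Per-pixel sample SD of July-August daily temperature for one year.

    Pixels with fewer than ``min_days`` valid days are returned as NaN.
    """
    days = _summer_days(daily_t, year)
    n = np.isfinite(days).sum("doy")
    sd = days.std("doy", ddof=1, skipna=True)
    out = sd.where(n >= min_days)
    out.attrs["units"] = daily_t.attrs.get("units", "")
    return out


def temp_variability_trend(daily_t: xr.DataArray, years,
                           mask: xr.DataArray | None = None) -> dict:
    """Regional summer daily-T SD per year and its OLS trend.

    Used to check that the variance of daily summer temperature is stable
    over the record (so a changing temperature *distribution width* cannot
    explain shifts in correlation).
    """
    years = np.asarray(years, int)
    series = np.array([regional_mean(temp_variability(daily_t, int(y)), mask)
                       for y in years])
    res = sps.linregress(years.astype(float), series)
    return {"years": years, "sd": series,
            "slope": float(res.slope), "p": float(res.pvalue)}


# ---------------------------------------------------------------------------
# NetCDF I/O (classic format via the scipy backend)


def write_netcdf(data: xr.DataArray | xr.Dataset, path, name: str = "field") -> None:
    """Write a grid to classic NetCDF; a units attribute is required."""
    if isinstance(data, xr.DataArray):
        if "units" not in data.attrs:
            raise ValueError("units attribute required before writing")
        data = data.to_dataset(name=data.name or name)
    ds = data
    for v in ds.data_vars.values():
        if "units" not in v.attrs:
            raise ValueError(f"variable {v.name!r} lacks a units attribute")
    enc = {v: {"dtype": "float64"} for v in ds.data_vars
           if ds[v].dtype.kind == "f"}
    bool_vars = [v for v in ds.data_vars if ds[v].dtype == bool]
    for v in bool_vars:
        ds[v] = ds[v].astype("int8")
        ds[v].attrs.setdefault("units", "1")
    ds.to_netcdf(path, engine="scipy", encoding=enc)


def read_netcdf(path) -> xr.Dataset:
    ds = xr.open_dataset(path, engine="scipy")
    ds.load()
    ds.close()
    return ds
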