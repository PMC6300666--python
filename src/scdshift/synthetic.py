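"""Synthetic Arctic CO2 / climate world with known ground truth.

The generator emulates the statistical structure of a high-latitude CO2
monitoring record (Barrow-like) coupled to gridded climate fields, so the
whole analysis chain can be exercised against a known truth:

* a daily CO2 record = quadratic growth + four-harmonic seasonal cycle,
  whose July–August drawdown anomaly in each year is a linear function of
  the regional summer temperature anomaly, with a period-dependent coupling
  coefficient (``coupling_early`` before ``break_year``, ``coupling_late``
  after), plus AR(1) synoptic noise, random gaps and injected spike outliers;
* monthly temperature / precipitation / cloud fields and daily temperature
  on a regular lat-lon grid, all sharing the regional interannual temperature
  mode used to drive the CO2 drawdown;
* summer NDVI coupled to temperature with a period-dependent slope and an
  optional heat-stress penalty per extreme warm day, heterotrophic
  respiration following a Q10 law, a smooth station-footprint sensitivity
  field, and a summer sea-ice-extent scalar series.

Everything is reproducible: the same :class:`TruthParams` (including its
seed) regenerates identical outputs.  All series use a 365-day calendar.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import xarray as xr
from scipy.ndimage import gaussian_filter1d

from .curvefit import CO2Series, FLAG_MISSING, FLAG_RETAINED
from .timeaxis import AUG31, DAYS_PER_YEAR, JUL7, noleap_axis

# independent RNG streams derived from the root seed
_STREAM_TANOM = 0
_STREAM_SCD_NOISE = 1
_STREAM_AR1 = 2
_STREAM_GAPS = 3
_STREAM_OUTLIERS = 4
_STREAM_T_FIELD = 5
_STREAM_PRECIP = 6
_STREAM_CLOUD = 7
_STREAM_DAILY_T = 8
_STREAM_NDVI = 9
_STREAM_HR = 10
_STREAM_SIE = 11

#: default seasonal harmonics (amplitude ppm, phase rad) giving a Barrow-like
#: cycle: climatological spring zero-crossing near DOY 177-178, trough near
#: DOY 235, ~10.6 ppm drawdown between early July and late August.
DEFAULT_HARMONICS = (
    (9.2938, 1.1551),
    (3.5444, -1.0838),
    (1.4163, 1.7998),
    (0.1585, -1.2473),
)


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth parameters of the synthetic world (see module docstring).

    Couplings are in ppm of summer drawdown per degC of regional summer
    temperature anomaly; ``ar1_sigma`` is the marginal (stationary) standard
    deviation of the synoptic noise.
    """

    year_start: int = 1979
    year_end: int = 2012
    base_conc: float = 345.0            # ppm at the start of the record
    trend_lin: float = 1.7              # ppm / year
    trend_quad: float = 0.011           # ppm / year^2
    harmonic_amps: tuple = DEFAULT_HARMONICS
    coupling_early: float = 0.0         # ppm / degC before break_year
    coupling_late: float = -2.0         # ppm / degC from break_year on
    break_year: int = 1996
    t_anom_sd: float = 1.0              # degC, interannual regional mode
    scd_noise_sd: float = 0.8           # ppm, drawdown noise unrelated to T
    ar1_rho: float = 0.65
    ar1_sigma: float = 1.5              # ppm
    gap_fraction: float = 0.05
    outlier_rate: float = 0.003         # per-day probability
    outlier_scale: float = 1.0          # multiplies the 5-20 sigma spike size
    # grid: 20 x 40 pixels over 50-80 N, all longitudes
    lat_min: float = 50.0
    lat_max: float = 80.0
    n_lat: int = 20
    lon_min: float = 0.0
    lon_max: float = 360.0
    n_lon: int = 40
    # climate fields
    warming_trend: float = 0.025        # degC / year added to T fields
    t_pixel_noise_sd: float = 0.8       # degC, spatially correlated
    noise_corr_pixels: float = 1.5      # smoothing length of pixel noise
    t_seasonal_amp: float = 15.0        # degC annual cycle amplitude
    precip_clim: float = 55.0           # mm / month
    precip_anom_sd: float = 8.0
    precip_pixel_noise_sd: float = 6.0
    cloud_clim: float = 65.0            # %
    cloud_anom_sd: float = 4.0
    cloud_pixel_noise_sd: float = 3.0
    daily_t_sd: float = 3.0             # degC day-to-day variability
    # vegetation / respiration
    ndvi_beta_early: float = 0.03       # NDVI / degC before break_year
    ndvi_beta_late: float = 0.0
    heat_penalty: float = 0.0           # NDVI per extreme warm day
    ndvi_noise_sd: float = 0.02
    hr_base: float = 60.0               # respiration at climatological T
    hr_q10: float = 2.0
    hr_noise_sd: float = 2.0
    sie_base: float = 8.5               # million km^2
    sie_trend: float = -0.04            # per year
    sie_t_coupling: float = -0.3        # per degC
    sie_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.year_end - self.year_start + 1 < 3:
            raise ValueError("need at least 3 years")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must be in [0, 1)")
        if not 0 <= self.gap_fraction < 1:
            raise ValueError("gap_fraction must be in [0, 1)")
        if not (-90 <= self.lat_min < self.lat_max <= 90):
            raise ValueError("latitudes must satisfy -90 <= lat_min < lat_max <= 90")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1

    @property
    def lats(self) -> np.ndarray:
        step = (self.lat_max - self.lat_min) / self.n_lat
        return self.lat_min + step * (np.arange(self.n_lat) + 0.5)

    @property
    def lons(self) -> np.ndarray:
        step = (self.lon_max - self.lon_min) / self.n_lon
        return self.lon_min + step * (np.arange(self.n_lon) + 0.5)

    def coupling_for(self, years: np.ndarray) -> np.ndarray:
        years = np.asarray(years)
        return np.where(years < self.break_year, self.coupling_early, self.coupling_late)

    def ndvi_beta_for(self, years: np.ndarray) -> np.ndarray:
        years = np.asarray(years)
        return np.where(years < self.break_year, self.ndvi_beta_early, self.ndvi_beta_late)


@dataclass
class TruthRecord:
    """Per-year ground truth stored alongside generated data."""

    years: np.ndarray
    t_anom: np.ndarray                 # degC, the shared interannual mode
    coupling: np.ndarray               # ppm / degC actually applied
    drawdown_anom: np.ndarray          # ppm, imposed SCD anomaly (incl. noise)
    outlier_days: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def to_dict(self) -> dict:
        return {
            "years": self.years.tolist(),
            "t_anom_degC": self.t_anom.tolist(),
            "coupling_ppm_per_degC": self.coupling.tolist(),
            "drawdown_anom_ppm": self.drawdown_anom.tolist(),
            "outlier_days": self.outlier_days.tolist(),
        }

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _rng(params: TruthParams, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(params.seed), stream])


def regional_t_anom(params: TruthParams) -> np.ndarray:
    """The shared interannual summer temperature mode (degC, one per year)."""
    return _rng(params, _STREAM_TANOM).normal(0.0, params.t_anom_sd, params.n_years)


def seasonal_cycle(params: TruthParams, doy: np.ndarray) -> np.ndarray:
    """Baseline detrended seasonal cycle (ppm) at integer day-of-year."""
    out = np.zeros(np.shape(doy), dtype=float)
    for k, (amp, phase) in enumerate(params.harmonic_amps, start=1):
        out += amp * np.cos(2 * np.pi * k * np.asarray(doy) / DAYS_PER_YEAR - phase)
    return out


def _drawdown_ramp(doy: np.ndarray) -> np.ndarray:
    """Smooth 0->1 modulation of the July-August descending limb.

    Zero through the first week of July (so the early-July window is
    untouched), one across the last week of August (so the imposed anomaly is
    realized in full by then), relaxing back to zero through autumn to keep
    the curve continuous across years.
    """
    doy = np.asarray(doy, dtype=float)
    ramp = np.zeros_like(doy)
    rise = (doy > JUL7) & (doy < 237)
    ramp[rise] = 0.5 * (1 - np.cos(np.pi * (doy[rise] - JUL7) / (237 - JUL7)))
    ramp[(doy >= 237) & (doy <= AUG31)] = 1.0
    decay = (doy > AUG31) & (doy < 320)
    ramp[decay] = 0.5 * (1 + np.cos(np.pi * (doy[decay] - AUG31) / (320 - AUG31)))
    return ramp


def generate_co2_series(params: TruthParams) -> tuple[CO2Series, TruthRecord]:
    """Daily CO2 record with temperature-coupled summer drawdown anomalies."""
    t, year, doy = noleap_axis(params.year_start, params.year_end)
    yrs_f = t / DAYS_PER_YEAR
    conc = (params.base_conc + params.trend_lin * yrs_f
            + params.trend_quad * yrs_f**2 + seasonal_cycle(params, doy))

    t_anom = regional_t_anom(params)
    coupling = params.coupling_for(params.years)
    scd_noise = _rng(params, _STREAM_SCD_NOISE).normal(0.0, params.scd_noise_sd,
                                                       params.n_years)
    drawdown_anom = coupling * t_anom + scd_noise
    year_idx = year - params.year_start
    conc -= drawdown_anom[year_idx] * _drawdown_ramp(doy)

    if params.ar1_sigma > 0:
        eps = _rng(params, _STREAM_AR1).normal(0.0, 1.0, t.size)
        innov_sd = params.ar1_sigma * np.sqrt(1.0 - params.ar1_rho**2)
        noise = np.empty(t.size)
        noise[0] = params.ar1_sigma * eps[0]
        for i in range(1, t.size):
            noise[i] = params.ar1_rho * noise[i - 1] + innov_sd * eps[i]
        conc += noise

    flag = np.full(t.size, FLAG_RETAINED, dtype=int)
    if params.gap_fraction > 0:
        gaps = _rng(params, _STREAM_GAPS).random(t.size) < params.gap_fraction
        flag[gaps] = FLAG_MISSING
        conc[gaps] = np.nan

    outlier_days = np.array([], dtype=int)
    if params.outlier_rate > 0:
        rng = _rng(params, _STREAM_OUTLIERS)
        hit = (rng.random(t.size) < params.outlier_rate) & (flag == FLAG_RETAINED)
        outlier_days = np.flatnonzero(hit)
        if outlier_days.size:
            ref_sd = params.ar1_sigma if params.ar1_sigma > 0 else 1.0
            size = rng.uniform(5.0, 20.0, outlier_days.size)
            sign = rng.choice([-1.0, 1.0], outlier_days.size)
            conc[outlier_days] += sign * size * ref_sd * params.outlier_scale

    series = CO2Series(t, year, doy, conc, flag, cadence="daily", calendar="noleap")
    truth = TruthRecord(params.years, t_anom, coupling, drawdown_anom, outlier_days)
    return series, truth


# ---------------------------------------------------------------------------
# gridded fields


def _mid_month_doy() -> np.ndarray:
    edges = np.array([0, 31, 59, 90, 120, 151, 181, 212, 243, 273, 304, 334, 365])
    return 0.5 * (edges[:-1] + edges[1:] + 1)


def _daily_t_climatology(params: TruthParams, doy: np.ndarray,
                         lats: np.ndarray) -> np.ndarray:
    """(doy, lat) temperature climatology: warmest in mid-July, colder poleward."""
    lat_mean = 2.0 - 0.5 * (lats - 50.0)
    cycle = params.t_seasonal_amp * np.cos(2 * np.pi * (np.asarray(doy) - 196) / DAYS_PER_YEAR)
    return lat_mean[None, :] + cycle[:, None]


def _correlated_noise(rng: np.random.Generator, shape: tuple, sd: float,
                      corr_pixels: float) -> np.ndarray:
    """Spatially correlated pixel noise; last two axes are (lat, lon)."""
    if sd == 0:
        return np.zeros(shape)
    white = rng.normal(0.0, 1.0, shape)
    sm = gaussian_filter1d(white, corr_pixels, axis=-2, mode="nearest")
    sm = gaussian_filter1d(sm, corr_pixels, axis=-1, mode="wrap")
    scale = sm.std()
    return sd * sm / scale if scale > 0 else sm


def generate_climate_fields(params: TruthParams) -> xr.Dataset:
    """Monthly T / precipitation / cloud plus daily T on the synthetic grid.

    All fields carry the same regional interannual mode (``t_anom``) so the
    cos(lat)-weighted summer-mean temperature anomaly reproduces the series
    that drives the CO2 drawdown; precipitation and cloud get independent
    interannual modes.
    """
    lats, lons = params.lats, params.lons
    years = params.years
    t_anom = regional_t_anom(params)
    trend = params.warming_trend * (years - params.year_start)

    months = np.arange(1, 13)
    clim_md = _daily_t_climatology(params, _mid_month_doy(), lats)  # (month, lat)
    tas = (clim_md[None, :, :, None]
           + (t_anom + trend)[:, None, None, None]
           + _correlated_noise(_rng(params, _STREAM_T_FIELD),
                               (params.n_years, 12, params.n_lat, params.n_lon),
                               params.t_pixel_noise_sd, params.noise_corr_pixels))

    rng_p = _rng(params, _STREAM_PRECIP)
    p_mode = rng_p.normal(0.0, params.precip_anom_sd, params.n_years)
    pr = (params.precip_clim + p_mode[:, None, None, None]
          + _correlated_noise(rng_p, tas.shape, params.precip_pixel_noise_sd,
                              params.noise_corr_pixels))
    pr = np.maximum(pr, 0.0)

    rng_c = _rng(params, _STREAM_CLOUD)
    c_mode = rng_c.normal(0.0, params.cloud_anom_sd, params.n_years)
    cloud = (params.cloud_clim + c_mode[:, None, None, None]
             + _correlated_noise(rng_c, tas.shape, params.cloud_pixel_noise_sd,
                                 params.noise_corr_pixels))
    cloud = np.clip(cloud, 0.0, 100.0)

    doys = np.arange(1, DAYS_PER_YEAR + 1)
    daily_clim = _daily_t_climatology(params, doys, lats)  # (doy, lat)
    rng_d = _rng(params, _STREAM_DAILY_T)
    tas_daily = (daily_clim[None, :, :, None]
                 + (t_anom + trend)[:, None, None, None]
                 + rng_d.normal(0.0, params.daily_t_sd,
                                (params.n_years, DAYS_PER_YEAR,
                                 params.n_lat, params.n_lon))).astype(np.float32)

    coords = {"year": years, "month": months, "doy": doys, "lat": lats, "lon": lons}
    ds = xr.Dataset(
        {
            "tas": (("year", "month", "lat", "lon"), tas, {"units": "degC"}),
            "pr": (("year", "month", "lat", "lon"), pr, {"units": "mm month-1"}),
            "cloud": (("year", "month", "lat", "lon"), cloud, {"units": "%"}),
            "tas_daily": (("year", "doy", "lat", "lon"), tas_daily, {"units": "degC"}),
        },
        coords=coords,
    )
    ds["lat"].attrs["units"] = "degrees_north"
    ds["lon"].attrs["units"] = "degrees_east"
    return ds


def _summer_pixel_t(tas: xr.DataArray) -> xr.DataArray:
    return tas.sel(month=[7, 8]).mean("month")


def ndvi_climatology(params: TruthParams) -> xr.DataArray:
    """Long-term mean summer NDVI: green in the south, sparse near 80N."""
    clim = 0.72 - 0.021 * (params.lats - 50.0)
    vals = np.broadcast_to(clim[:, None], (params.n_lat, params.n_lon)).copy()
    return xr.DataArray(vals, coords={"lat": params.lats, "lon": params.lons},
                        dims=("lat", "lon"), attrs={"units": "1"})


def generate_ndvi(params: TruthParams, tas: xr.DataArray,
                  extreme_days: xr.DataArray | None = None) -> xr.DataArray:
    """Summer NDVI per year, coupled to summer temperature anomalies.

    NDVI = climatology + beta(period) * T_anomaly - heat_penalty * n_extreme
    + noise, clipped to [-0.1, 1].  ``tas`` is the monthly temperature field.
    """
    t_sum = _summer_pixel_t(tas)
    anom = t_sum - t_sum.mean("year")
    years = tas["year"].values
    beta = params.ndvi_beta_for(years)
    clim = ndvi_climatology(params)
    ndvi = clim + xr.DataArray(beta, coords={"year": years}, dims=("year",)) * anom
    if extreme_days is not None and params.heat_penalty != 0:
        if not (np.array_equal(extreme_days["lat"], tas["lat"])
                and np.array_equal(extreme_days["lon"], tas["lon"])):
            raise ValueError("extreme-day grid does not match the temperature grid")
        ndvi = ndvi - params.heat_penalty * extreme_days
    if params.ndvi_noise_sd > 0:
        noise = _correlated_noise(_rng(params, _STREAM_NDVI), ndvi.shape,
                                  params.ndvi_noise_sd, params.noise_corr_pixels)
        ndvi = ndvi + noise
    out = ndvi.clip(-0.1, 1.0).transpose("year", "lat", "lon")
    out.attrs["units"] = "1"
    return out


def generate_hr(params: TruthParams, tas: xr.DataArray) -> xr.DataArray:
    """Summer heterotrophic respiration via a Q10 law, strictly positive."""
    t_sum = _summer_pixel_t(tas)
    t0 = t_sum.mean("year")
    hr = params.hr_base * params.hr_q10 ** ((t_sum - t0) / 10.0)
    if params.hr_noise_sd > 0:
        hr = hr + _correlated_noise(_rng(params, _STREAM_HR), hr.shape,
                                    params.hr_noise_sd, params.noise_corr_pixels)
    out = hr.clip(min=1e-6).transpose("year", "lat", "lon")
    out.attrs["units"] = "gC m-2"
    return out


def generate_footprint(params: TruthParams, center_lat: float = 71.0,
                       center_lon: float = 203.0, sigma_lat: float = 8.0,
                       sigma_lon: float = 35.0) -> xr.DataArray:
    """Smooth non-negative station sensitivity field, max-normalized to 1.

    A single Gaussian bump centered near the station (Barrow-like default),
    wrapping in longitude.
    """
    lats, lons = params.lats, params.lons
    dlon = (lons - center_lon + 180.0) % 360.0 - 180.0
    bump = np.exp(-0.5 * (((lats - center_lat) / sigma_lat) ** 2)[:, None]
                  - 0.5 * ((dlon / sigma_lon) ** 2)[None, :])
    bump /= bump.max()
    return xr.DataArray(bump, coords={"lat": lats, "lon": lons},
                        dims=("lat", "lon"),
                        attrs={"units": "1", "long_name": "station footprint sensitivity"})


def generate_sie(params: TruthParams) -> np.ndarray:
    """Summer sea-ice extent (million km^2): declining, weakly tied to T."""
    t_anom = regional_t_anom(params)
    noise = _rng(params, _STREAM_SIE).normal(0.0, params.sie_noise_sd, params.n_years)
    return (params.sie_base + params.sie_trend * (params.years - params.year_start)
            + params.sie_t_coupling * t_anom + noise)


def simulate_world(params: TruthParams) -> dict:
    """Generate every pipeline input in one call.

    Returns a dict with keys ``co2``, ``truth``, ``climate`` (Dataset),
    ``ndvi``, ``hr``, ``footprint`` (DataArrays), and ``sie`` (per-year array).
    """
    co2, truth = generate_co2_series(params)
    climate = generate_climate_fields(params)
    extreme = None
    if params.heat_penalty != 0:
        from .spatial import extreme_warm_days_all_years
        extreme = extreme_warm_days_all_years(climate["tas_daily"], params.years)
    ndvi = generate_ndvi(params, climate["tas"], extreme)
    return {
        "co2": co2,
        "truth": truth,
        "climate": climate,
        "ndvi": ndvi,
        "hr": generate_hr(params, climate["tas"]),
        "footprint": generate_footprint(params),
        "sie": generate_sie(params),
    }


def params_to_json(params: TruthParams, path) -> None:
    Path(path).write_text(json.dumps(asdict(params), indent=2))
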