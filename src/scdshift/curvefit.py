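"""Decomposition of an atmospheric CO2 record into trend and seasonal parts.

The procedure follows the classic curve-fitting approach used for flask and
in-situ CO2 station records: a quadratic polynomial (long-term trend) plus
four annual harmonics (mean seasonal cycle) is least-squares fitted to the
record, and the residuals are digitally filtered with two gap-aware Gaussian
smoothers specified by their full width at half maximum (FWHM):

* a short filter (default 45.66 days, i.e. 1.5 months) retaining synoptic-free
  intra-annual variability, and
* a long filter (default 390 days) capturing interannual trend variations.

The detrended seasonal curve is

    D(t) = harmonics(t) + [S(t) - L(t)]

with S and L the short- and long-filtered residuals, and the full trend is
polynomial(t) + L(t).  Records lying more than five standard deviations from
the fit are discarded before the final decomposition (daily data only; weekly
records from curated archives arrive pre-screened).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .timeaxis import DAYS_PER_YEAR, doy_noleap, month_day_from_doy

MISSING_SENTINEL = -999.99

FLAG_RETAINED = 0
FLAG_MISSING = 1
FLAG_OUTLIER = 2

_FLAG_NAMES = {FLAG_RETAINED: "retained", FLAG_MISSING: "missing", FLAG_OUTLIER: "outlier"}


# ---------------------------------------------------------------------------
# containers


@dataclass
class CO2Series:
    """A dated CO2 concentration record on a uniform daily or weekly cadence.

    ``t`` is the time axis in days since the first record.  ``conc`` is NaN
    where ``flag`` is not retained.  ``calendar`` is ``"noleap"`` for
    synthetic records (365-day years, annual period 365.0 d) or
    ``"gregorian"`` for real records (true day spacing, period 365.25 d).
    """

    t: np.ndarray
    year: np.ndarray
    doy: np.ndarray
    conc: np.ndarray
    flag: np.ndarray
    cadence: str = "daily"
    calendar: str = "noleap"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        self.year = np.asarray(self.year, dtype=int)
        self.doy = np.asarray(self.doy, dtype=int)
        self.flag = np.asarray(self.flag, dtype=int)
        if self.t.size == 0:
            raise ValueError("empty CO2 series")
        d = np.diff(self.t)
        if np.any(d <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.cadence not in ("daily", "weekly"):
            raise ValueError(f"unknown cadence {self.cadence!r}")
        if d.size:
            med = float(np.median(d))
            lo, hi = (0.5, 1.5) if self.cadence == "daily" else (5.0, 9.0)
            if not lo <= med <= hi:
                raise ValueError(
                    f"median spacing {med:.2f} d inconsistent with {self.cadence} cadence"
                )
        ret = self.flag == FLAG_RETAINED
        if not np.all(np.isfinite(self.conc[ret])):
            raise ValueError("non-finite concentration on a retained record")

    @property
    def period_days(self) -> float:
        return 365.0 if self.calendar == "noleap" else 365.25

    @property
    def retained(self) -> np.ndarray:
        return self.flag == FLAG_RETAINED

    @property
    def n_retained(self) -> int:
        return int(np.count_nonzero(self.retained))

    def copy(self) -> "CO2Series":
        return CO2Series(
            self.t.copy(), self.year.copy(), self.doy.copy(),
            self.conc.copy(), self.flag.copy(), self.cadence, self.calendar,
        )


@dataclass
class FunctionFit:
    """Quadratic + four-harmonic least-squares fit to a CO2 record.

    The polynomial is evaluated on a centered/scaled time variable internally
    for numerical stability; :attr:`poly` reports the equivalent coefficients
    (ppm, ppm day^-1, ppm day^-2) on the days-since-start axis.
    """

    poly_scaled: np.ndarray          # (3,) coefficients on tc = (t - tmid)/tscale
    tmid: float
    tscale: float
    t0: float
    harmonics: np.ndarray            # (n_harm, 2): cos, sin coefficients
    period_days: float
    residuals: np.ndarray            # at retained records
    t_retained: np.ndarray

    @property
    def poly(self) -> np.ndarray:
        a0, a1, a2 = self.poly_scaled
        c, s = self.tmid - self.t0, self.tscale
        return np.array([
            a0 - a1 * c / s + a2 * c**2 / s**2,
            a1 / s - 2 * a2 * c / s**2,
            a2 / s**2,
        ])

    def trend_at(self, t: np.ndarray) -> np.ndarray:
        tc = (np.asarray(t, float) - self.tmid) / self.tscale
        a0, a1, a2 = self.poly_scaled
        return a0 + a1 * tc + a2 * tc**2

    def harmonics_at(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        out = np.zeros_like(t)
        for k, (ck, sk) in enumerate(self.harmonics, start=1):
            w = 2 * np.pi * k * t / self.period_days
            out += ck * np.cos(w) + sk * np.sin(w)
        return out

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.trend_at(t) + self.harmonics_at(t)

    def harmonic_amplitudes(self) -> np.ndarray:
        return np.hypot(self.harmonics[:, 0], self.harmonics[:, 1])

    def summary(self) -> dict:
        return {
            "poly_ppm_per_day": [float(x) for x in self.poly],
            "harmonic_amplitudes_ppm": [float(x) for x in self.harmonic_amplitudes()],
            "period_days": self.period_days,
            "residual_sd_ppm": float(np.std(self.residuals)),
            "n_records": int(self.residuals.size),
        }


@dataclass
class CurveDecomposition:
    """Trend / detrended-seasonal split of a CO2 record on a full daily axis."""

    t: np.ndarray                    # integer days since series start
    year: np.ndarray
    doy: np.ndarray
    conc: np.ndarray                 # cleaned record on the daily axis (NaN at gaps)
    trend: np.ndarray                # polynomial + long-filtered residuals
    seasonal: np.ndarray             # D(t) = harmonics + (S - L)
    smooth_resid: np.ndarray         # S, short-filtered residuals
    fit: FunctionFit
    n_outliers_removed: int = 0
    edge: np.ndarray = field(default=None)  # lower-confidence first/last half-year

    def __post_init__(self) -> None:
        if self.edge is None:
            self.edge = np.zeros(self.t.size, dtype=bool)
            half = DAYS_PER_YEAR // 2
            self.edge[:half] = True
            self.edge[-half:] = True

    @property
    def years(self) -> np.ndarray:
        """Years fully covered by the daily axis."""
        yy, counts = np.unique(self.year, return_counts=True)
        return yy[counts >= DAYS_PER_YEAR]

    def seasonal_for(self, year: int, doy_lo: int = 1, doy_hi: int = DAYS_PER_YEAR):
        """(doy, D) for one year restricted to [doy_lo, doy_hi]."""
        m = (self.year == year) & (self.doy >= doy_lo) & (self.doy <= doy_hi)
        return self.doy[m], self.seasonal[m]

    def seasonal_climatology(self, years=None) -> np.ndarray:
        """Mean D by DOY (length 365) over the given (default: all full) years."""
        if years is None:
            years = self.years
        years = np.asarray(years)
        m = np.isin(self.year, years) & np.isfinite(self.seasonal)
        sums = np.zeros(DAYS_PER_YEAR)
        cnt = np.zeros(DAYS_PER_YEAR)
        np.add.at(sums, self.doy[m] - 1, self.seasonal[m])
        np.add.at(cnt, self.doy[m] - 1, 1.0)
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, sums / np.maximum(cnt, 1), np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "year": self.year,
            "doy": self.doy,
            "conc": self.conc,
            "trend": self.trend,
            "detrended_seasonal": self.seasonal,
            "edge": self.edge.astype(int),
        })

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    def write_fit_json(self, path) -> None:
        info = self.fit.summary()
        info["n_outliers_removed"] = self.n_outliers_removed
        Path(path).write_text(json.dumps(info, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# I/O


def _finalize(rows, cadence=None) -> CO2Series:
    rows.sort(key=lambda r: r[0])
    ords = np.array([r[0] for r in rows], dtype=float)
    if np.any(np.diff(ords) <= 0):
        raise ValueError("non-monotone (or duplicate) dates in CO2 file")
    years = np.array([r[1] for r in rows])
    doys = np.array([r[2] for r in rows])
    conc = np.array([r[3] for r in rows])
    flag = np.where(np.isfinite(conc), FLAG_RETAINED, FLAG_MISSING)
    if cadence is None:
        cadence = "daily" if np.median(np.diff(ords)) < 3 else "weekly"
    return CO2Series(ords - ords[0], years, doys, conc, flag,
                     cadence=cadence, calendar="gregorian")


def read_co2(path, dialect: str = "csv") -> CO2Series:
    """Read a CO2 record from disk.

    Dialects:
      * ``csv`` — two columns ``date,conc`` with ISO dates; header optional.
      * ``noaa-insitu-daily`` — whitespace columns ``year month day value
        [...]``; lines starting with ``#`` are comments.
      * ``globalview-weekly`` — same columns at weekly cadence.

    The sentinel value -999.99 marks missing data.  February 29 records are
    dropped (the analysis uses a stable 365-day day-of-year grid).
    """
    path = Path(path)
    text = path.read_text().splitlines()
    rows = []
    if dialect == "csv":
        for ln, line in enumerate(text, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if ln == 1 and parts[0].lower() in ("date", "time"):
                continue
            try:
                date = _dt.date.fromisoformat(parts[0].strip())
                value = float(parts[1])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path.name}:{ln}: unparseable line {line!r}") from exc
            if date.month == 2 and date.day == 29:
                continue
            if abs(value - MISSING_SENTINEL) < 1e-6:
                value = np.nan
            rows.append((date.toordinal(), date.year,
                         int(doy_noleap(date.month, date.day)), value))
    elif dialect in ("noaa-insitu-daily", "globalview-weekly"):
        for ln, line in enumerate(text, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                y, mo, d = int(parts[0]), int(parts[1]), int(parts[2])
                value = float(parts[3])
                date = _dt.date(y, mo, d)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path.name}:{ln}: unparseable line {line!r}") from exc
            if mo == 2 and d == 29:
                continue
            if abs(value - MISSING_SENTINEL) < 1e-6:
                value = np.nan
            rows.append((date.toordinal(), y, int(doy_noleap(mo, d)), value))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not rows:
        raise ValueError(f"{path}: no data records found")
    cadence = "weekly" if dialect == "globalview-weekly" else None
    return _finalize(rows, cadence)


def write_co2(series: CO2Series, path, dialect: str = "csv") -> None:
    """Write a series in the plain CSV dialect (values at 0.01 ppm precision)."""
    if dialect != "csv":
        raise ValueError("only the csv dialect is written")
    lines = ["date,conc"]
    for y, doy, c, f in zip(series.year, series.doy, series.conc, series.flag):
        mo, d = month_day_from_doy(int(doy))
        v = MISSING_SENTINEL if f != FLAG_RETAINED or not np.isfinite(c) else c
        lines.append(f"{y:04d}-{mo:02d}-{d:02d},{v:.2f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# fitting


def _design(t: np.ndarray, tmid: float, tscale: float, period: float,
            n_harmonics: int) -> np.ndarray:
    tc = (t - tmid) / tscale
    cols = [np.ones_like(t), tc, tc**2]
    for k in range(1, n_harmonics + 1):
        w = 2 * np.pi * k * t / period
        cols.append(np.cos(w))
        cols.append(np.sin(w))
    return np.column_stack(cols)


def fit_function(series: CO2Series, n_harmonics: int = 4) -> FunctionFit:
    """Least-squares quadratic + harmonic fit over retained records."""
    m = series.retained
    t = series.t[m]
    y = series.conc[m]
    if t.size < 2 or (t[-1] - t[0]) < 3 * series.period_days - 2:
        raise ValueError("need at least 3 full years of retained data")
    tmid = 0.5 * (t[0] + t[-1])
    tscale = max(0.5 * (t[-1] - t[0]), 1.0)
    X = _design(t, tmid, tscale, series.period_days, n_harmonics)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design matrix (degenerate time axis)")
    resid = y - X @ beta
    return FunctionFit(
        poly_scaled=beta[:3], tmid=tmid, tscale=tscale, t0=series.t[0],
        harmonics=beta[3:].reshape(-1, 2), period_days=series.period_days,
        residuals=resid, t_retained=t,
    )


def reject_outliers(series: CO2Series, k: float = 5.0,
                    max_iter: int = 5) -> tuple[CO2Series, FunctionFit]:
    """Iteratively flag records beyond ``k`` residual standard deviations.

    Refits after each pass until no new rejections (at most ``max_iter``
    passes).  Returns the cleaned series and the final fit.
    """
    work = series.copy()
    fit = fit_function(work)
    for _ in range(max_iter):
        sd = float(np.std(fit.residuals))
        if sd < 1e-9:  # numerically exact fit; nothing left to reject
            break
        bad = np.abs(fit.residuals) > k * sd
        if not bad.any():
            break
        idx = np.flatnonzero(work.retained)[bad]
        work.flag[idx] = FLAG_OUTLIER
        work.conc[idx] = np.nan
        if work.n_retained == 0:
            raise ValueError("outlier rejection removed every record")
        fit = fit_function(work)
    return work, fit


# ---------------------------------------------------------------------------
# filtering


def fwhm_sigma(fwhm_days: float) -> float:
    return fwhm_days / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def fwhm_filter(values: np.ndarray, fwhm_days: float,
                coverage_sigma: float = 3.0) -> np.ndarray:
    """Gap-aware Gaussian smoother on a uniform daily axis.

    ``values`` may contain NaN (gaps); kernel weights are renormalized over
    the available points.  Days with no data within ``coverage_sigma`` sigma
    are returned as NaN.  The kernel sigma is FWHM / (2 sqrt(2 ln 2)).
    """
    if fwhm_days <= 0:
        raise ValueError("fwhm_days must be positive")
    v = np.asarray(values, dtype=float)
    sigma = fwhm_sigma(fwhm_days)
    half = int(np.ceil(4.0 * sigma))
    x = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)

    mask = np.isfinite(v).astype(float)
    v0 = np.where(mask > 0, v, 0.0)
    num = fftconvolve(v0, kernel, mode="same")
    den = fftconvolve(mask, kernel, mode="same")

    cov_half = int(np.ceil(coverage_sigma * sigma))
    box = np.ones(2 * cov_half + 1)
    coverage = fftconvolve(mask, box, mode="same")

    out = np.full_like(v, np.nan)
    ok = (coverage > 0.5) & (den > 1e-12)
    out[ok] = num[ok] / den[ok]
    return out


# ---------------------------------------------------------------------------
# decomposition


SHORT_FWHM_DAYS = 45.66   # "1.5 months" = 1.5 * 365.25 / 12
LONG_FWHM_DAYS = 390.0


def decompose(series: CO2Series, outlier_k: float = 5.0,
              short_fwhm: float = SHORT_FWHM_DAYS,
              long_fwhm: float = LONG_FWHM_DAYS) -> CurveDecomposition:
    """Full trend/seasonal decomposition of a CO2 record.

    Daily records are screened for outliers first; weekly records (already
    quality-controlled upstream) skip the rejection step.  Output arrays are
    defined on every integer day from the first to the last record.
    """
    n_out = 0
    if series.cadence == "daily":
        cleaned, fit = reject_outliers(series, k=outlier_k)
        n_out = int(np.count_nonzero(cleaned.flag == FLAG_OUTLIER))
    else:
        cleaned, fit = series.copy(), fit_function(series)

    t0 = cleaned.t[0]
    t_axis = np.arange(0.0, np.ceil(cleaned.t[-1] - t0) + 1.0)

    # residuals placed on the daily axis
    res_daily = np.full(t_axis.size, np.nan)
    conc_daily = np.full(t_axis.size, np.nan)
    idx = np.rint(fit.t_retained - t0).astype(int)
    res_daily[idx] = fit.residuals
    conc_daily[idx] = cleaned.conc[cleaned.retained]

    S = fwhm_filter(res_daily, short_fwhm)
    L = fwhm_filter(res_daily, long_fwhm)

    trend = fit.trend_at(t_axis + t0) + L
    seasonal = fit.harmonics_at(t_axis + t0) + (S - L)

    year_axis, doy_axis = _axis_calendar(cleaned, t_axis)
    return CurveDecomposition(
        t=t_axis, year=year_axis, doy=doy_axis, conc=conc_daily,
        trend=trend, seasonal=seasonal, smooth_resid=S, fit=fit,
        n_outliers_removed=n_out,
    )


def _axis_calendar(series: CO2Series, t_axis: np.ndarray):
    """(year, doy) labels for each day of the decomposition axis."""
    if series.calendar == "noleap":
        start = (series.year[0] - 1) * DAYS_PER_YEAR + (series.doy[0] - 1)
        abs_day = start + t_axis.astype(int)
        return abs_day // DAYS_PER_YEAR + 1, abs_day % DAYS_PER_YEAR + 1
    # gregorian: walk real dates; Feb 29 shares DOY 59 with Feb 28
    mo0, d0 = month_day_from_doy(int(series.doy[0]))
    start_date = _dt.date(int(series.year[0]), mo0, d0)
    years = np.empty(t_axis.size, dtype=int)
    doys = np.empty(t_axis.size, dtype=int)
    for i, dt_off in enumerate(t_axis.astype(int)):
        d = start_date + _dt.timedelta(days=int(dt_off))
        years[i] = d.year
        if d.month == 2 and d.day == 29:
            doys[i] = 59
        else:
            doys[i] = int(doy_noleap(d.month, d.day))
    return years, doys
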