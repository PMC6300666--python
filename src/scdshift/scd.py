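"""Summer CO2 drawdown (SCD) and seasonal-cycle phenology dates.

SCD is the drop in the detrended seasonal CO2 curve D(t) through the summer,
a proxy for net summer carbon uptake by the upwind land region.  Three
definitions are supported:

* ``fixed-window`` — mean D over July 1-7 minus mean D over August 25-31
  (the headline definition; positive = drawdown);
* ``climatological-dates`` — D at the climatological spring zero-crossing
  date minus D at the climatological trough date;
* ``annual-dates`` — same, but with the zero-crossing and trough dates
  located separately in each year.

The spring zero-crossing is the day D crosses zero downward (fractional, by
linear interpolation; if several crossings occur, the one nearest the
climatological DOY 178 is used).  The trough is the day of minimum D within
DOY 150-300, refined to a fractional day by local quadratic interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .curvefit import CurveDecomposition
from .timeaxis import AUG25, AUG31, JUL1, JUL7

METHODS = ("fixed-window", "climatological-dates", "annual-dates")

ZC_SEARCH = (100, 300)       # DOY range searched for the spring zero-crossing
TROUGH_SEARCH = (150, 300)   # DOY range searched for the seasonal minimum
ZC_REFERENCE_DOY = 178.0     # tie-break target for multiple crossings


@dataclass
class SCDRecord:
    year: int
    scd: float                  # ppm
    method: str
    window_start: float         # DOY
    window_end: float           # DOY

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown SCD method {self.method!r}")
        if not self.window_start < self.window_end:
            raise ValueError("window_start must precede window_end")
        if not np.isfinite(self.scd):
            raise ValueError("non-finite SCD")


@dataclass
class PhenoDates:
    label: str                  # a year, or "climatology"
    zero_crossing_doy: float
    trough_doy: float

    def __post_init__(self) -> None:
        for d in (self.zero_crossing_doy, self.trough_doy):
            if not 1 <= d <= 365:
                raise ValueError(f"DOY {d} outside 1..365")
        if self.zero_crossing_doy >= self.trough_doy:
            raise ValueError("zero-crossing must precede the trough")


def _year_curve(decomp: CurveDecomposition, year: int) -> tuple[np.ndarray, np.ndarray]:
    doy, d = decomp.seasonal_for(year)
    if doy.size == 0:
        raise ValueError(f"year {year} not covered by the decomposition")
    return doy, d


def scd_fixed_window(decomp: CurveDecomposition, year: int) -> SCDRecord:
    """SCD as mean D over July 1-7 minus mean D over August 25-31."""
    doy, d = _year_curve(decomp, year)
    scd_val = None
    means = []
    for lo, hi in ((JUL1, JUL7), (AUG25, AUG31)):
        m = (doy >= lo) & (doy <= hi)
        vals = d[m]
        missing = sorted(set(range(lo, hi + 1)) - set(doy[m][np.isfinite(vals)]))
        if missing or vals.size < (hi - lo + 1):
            raise ValueError(f"year {year}: missing D values on DOY {missing}")
        means.append(vals.mean())
    scd_val = means[0] - means[1]
    return SCDRecord(year, float(scd_val), "fixed-window", JUL1, AUG31)


def _downward_crossings(doy: np.ndarray, d: np.ndarray,
                        lo: int, hi: int) -> np.ndarray:
    """Fractional DOYs of downward zero crossings of D within [lo, hi]."""
    m = (doy >= lo) & (doy <= hi) & np.isfinite(d)
    dd, vv = doy[m].astype(float), d[m]
    out = []
    for i in range(dd.size - 1):
        if vv[i] > 0 >= vv[i + 1]:
            frac = vv[i] / (vv[i] - vv[i + 1])
            out.append(dd[i] + frac * (dd[i + 1] - dd[i]))
    return np.array(out)


def _trough(doy: np.ndarray, d: np.ndarray, lo: int, hi: int) -> float:
    """Fractional DOY of the minimum of D in [lo, hi] (earliest on ties)."""
    m = (doy >= lo) & (doy <= hi) & np.isfinite(d)
    dd, vv = doy[m].astype(float), d[m]
    if dd.size == 0:
        raise ValueError("no data in the trough search range")
    i = int(np.argmin(vv))  # argmin returns the first minimum on ties
    if 0 < i < dd.size - 1:
        # quadratic refinement through the three points around the minimum
        y0, y1, y2 = vv[i - 1], vv[i], vv[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom > 0:
            return float(dd[i] + 0.5 * (y0 - y2) / denom)
    return float(dd[i])


def pheno_dates(decomp: CurveDecomposition, year: int | None = None,
                years=None) -> PhenoDates:
    """Spring zero-crossing and trough dates for one year or the climatology.

    With ``year=None`` the multi-year mean D curve over ``years`` (default:
    every fully covered year) is used and the label is ``"climatology"``.
    """
    if year is not None:
        doy, d = _year_curve(decomp, year)
        label = str(year)
    else:
        d = decomp.seasonal_climatology(years)
        doy = np.arange(1, d.size + 1)
        label = "climatology"
    crossings = _downward_crossings(doy, d, *ZC_SEARCH)
    if crossings.size == 0:
        raise ValueError(f"{label}: no downward zero crossing in DOY "
                         f"{ZC_SEARCH[0]}-{ZC_SEARCH[1]}")
    zc = float(crossings[np.argmin(np.abs(crossings - ZC_REFERENCE_DOY))])
    trough = _trough(doy, d, *TROUGH_SEARCH)
    return PhenoDates(label, zc, trough)


def _interp_d(doy: np.ndarray, d: np.ndarray, at: float) -> float:
    m = np.isfinite(d)
    if not m.any():
        raise ValueError("no finite D values for interpolation")
    dd, vv = doy[m].astype(float), d[m]
    if not dd[0] <= at <= dd[-1]:
        raise ValueError(f"DOY {at} outside coverage [{dd[0]}, {dd[-1]}]")
    return float(np.interp(at, dd, vv))


def scd_between_dates(decomp: CurveDecomposition, year: int,
                      d1: float, d2: float,
                      method: str = "climatological-dates") -> SCDRecord:
    """SCD as D(d1) - D(d2) with D interpolated at fractional DOYs."""
    if not d1 < d2:
        raise ValueError("d1 must precede d2 (degenerate window)")
    doy, d = _year_curve(decomp, year)
    val = _interp_d(doy, d, d1) - _interp_d(doy, d, d2)
    return SCDRecord(year, val, method, d1, d2)


def scd_series(decomp: CurveDecomposition, method: str = "fixed-window",
               years=None) -> list[SCDRecord]:
    """Per-year SCD records under the given definition.

    For ``climatological-dates`` the zero-crossing/trough dates are located
    once on the multi-year mean curve; for ``annual-dates`` they are located
    in each year separately.
    """
    if method not in METHODS:
        raise ValueError(f"unknown SCD method {method!r}")
    if years is None:
        years = decomp.years
    if method == "fixed-window":
        return [scd_fixed_window(decomp, int(y)) for y in years]
    if method == "climatological-dates":
        dates = pheno_dates(decomp, years=years)
        return [scd_between_dates(decomp, int(y), dates.zero_crossing_doy,
                                  dates.trough_doy, method) for y in years]
    records = []
    for y in years:
        dates = pheno_dates(decomp, year=int(y))
        records.append(scd_between_dates(decomp, int(y), dates.zero_crossing_doy,
                                         dates.trough_doy, method))
    return records


def date_trend(years: np.ndarray, doys: np.ndarray) -> tuple[float, float]:
    """OLS trend (day / year) of a phenology date series, with its p-value."""
    years = np.asarray(years, float)
    doys = np.asarray(doys, float)
    if years.size < 5:
        raise ValueError("need at least 5 years for a date trend")
    res = sps.linregress(years, doys)
    return float(res.slope), float(res.pvalue)


def records_to_frame(records: list[SCDRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "year": r.year, "method": r.method, "scd_ppm": r.scd,
        "window_start": r.window_start, "window_end": r.window_end,
    } for r in records])
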