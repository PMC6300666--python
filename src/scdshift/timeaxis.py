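"""365-day ("noleap") calendar helpers.

All analysis in this package runs on a 365-day year: February 29 is dropped
when real calendar data are read, so that a given day-of-year (DOY) always
refers to the same calendar date.  Key summer landmarks:

* July 1–7   -> DOY 182–188 (the "first week of July")
* August 25–31 -> DOY 237–243 (the "last week of August")
"""

from __future__ import annotations

import numpy as np

DAYS_PER_YEAR = 365

#: cumulative days before each month (noleap), index 1..12
_MONTH_OFFSET = np.array([0, 0, 31, 59, 90, 120, 151, 181, 212, 243, 273, 304, 334])

JUL1 = 182
JUL7 = 188
AUG25 = 237
AUG31 = 243

#: Jul-Aug = DOY 182..243 inclusive -> 62 days
SUMMER_DOYS = np.arange(JUL1, AUG31 + 1)


def doy_noleap(month: int | np.ndarray, day: int | np.ndarray) -> np.ndarray:
    """Day of year in the 365-day calendar (Feb 29 has no DOY)."""
    return _MONTH_OFFSET[np.asarray(month)] + np.asarray(day)


def month_day_from_doy(doy: int) -> tuple[int, int]:
    """Inverse of :func:`doy_noleap` for a single DOY in 1..365."""
    if not 1 <= doy <= DAYS_PER_YEAR:
        raise ValueError(f"DOY {doy} outside 1..365")
    month = int(np.searchsorted(_MONTH_OFFSET[1:], doy, side="left"))
    return month, int(doy - _MONTH_OFFSET[month])


def noleap_axis(year_start: int, year_end: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Daily axis for whole years [year_start, year_end].

    Returns (t, year, doy) with t in integer days since Jan 1 of year_start.
    """
    if year_end < year_start:
        raise ValueError("year_end before year_start")
    n_years = year_end - year_start + 1
    year = np.repeat(np.arange(year_start, year_end + 1), DAYS_PER_YEAR)
    doy = np.tile(np.arange(1, DAYS_PER_YEAR + 1), n_years)
    t = np.arange(n_years * DAYS_PER_YEAR, dtype=float)
    return t, year, doy
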