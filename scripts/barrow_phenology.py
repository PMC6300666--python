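#!/usr/bin/env python
"""Phenology and drawdown statistics for a real NOAA Barrow CO2 record.

This script needs an observational input file that must be downloaded
separately (it is not bundled with the package), e.g. the NOAA GML in-situ
daily averages for Barrow (BRW):

    https://gml.noaa.gov/aftp/data/trace_gases/co2/in-situ/surface/brw/

Given that file it decomposes the record, reports the climatological
zero-crossing and trough dates of the detrended seasonal curve, their annual
trends over a chosen span, and writes the per-year summer drawdown series.

Usage:
    python scripts/barrow_phenology.py co2_brw_surface-insitu_1_ccgg_DailyData.txt \
        --dialect noaa-insitu-daily --start 1979 --end 2012 --outdir brw_out
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

from scdshift import date_trend, decompose, pheno_dates, read_co2, scd_series
from scdshift.scd import records_to_frame


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("input", type=Path, help="downloaded NOAA daily CO2 file")
    ap.add_argument("--dialect", default="noaa-insitu-daily",
                    choices=["csv", "noaa-insitu-daily", "globalview-weekly"])
    ap.add_argument("--start", type=int, default=1979)
    ap.add_argument("--end", type=int, default=2012)
    ap.add_argument("--outdir", type=Path, default=Path("barrow_out"))
    args = ap.parse_args()

    series = read_co2(args.input, args.dialect)
    decomp = decompose(series)
    years = np.array([y for y in decomp.years
                      if args.start <= y <= args.end])
    if years.size < 5:
        raise SystemExit(f"only {years.size} fully covered years in "
                         f"{args.start}-{args.end}; need at least 5")

    clim = pheno_dates(decomp)
    annual = [pheno_dates(decomp, year=int(y)) for y in years]
    zc = np.array([d.zero_crossing_doy for d in annual])
    trough = np.array([d.trough_doy for d in annual])
    zc_slope, zc_p = date_trend(years, zc)
    tr_slope, tr_p = date_trend(years, trough)

    out = {
        "years": [int(years[0]), int(years[-1])],
        "n_years": int(years.size),
        "climatological_zero_crossing_doy": clim.zero_crossing_doy,
        "climatological_trough_doy": clim.trough_doy,
        "zero_crossing_advance_days_per_year": -zc_slope,
        "zero_crossing_trend_p": zc_p,
        "trough_advance_days_per_year": -tr_slope,
        "trough_trend_p": tr_p,
        "n_outliers_removed": decomp.n_outliers_removed,
    }

    args.outdir.mkdir(parents=True, exist_ok=True)
    (args.outdir / "phenology.json").write_text(
        json.dumps(out, indent=2) + "\n")
    records = scd_series(decomp, "fixed-window", years)
    records_to_frame(records).to_csv(args.outdir / "scd.csv", index=False)
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
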