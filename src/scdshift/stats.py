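"""Detrended partial correlations, subsampling, sensitivities, comparisons.

The central diagnostic is the partial correlation between summer CO2
drawdown (SCD) and regional summer temperature, controlling for summer
precipitation and cloudiness (R_SCD-T), computed separately over an earlier
and a later period with all variables linearly detrended within each period.
The companion sensitivity gamma_SCD-T is the temperature coefficient of a
multiple regression of SCD on temperature, precipitation and cloud.

Sampling uncertainty of a period's correlation is characterized by the
distribution of the statistic over subsamples of m of the n years (all
C(n, m) subsets when enumerable, random draws otherwise), and periods are
compared with a Welch two-sample t-test on those distributions (or a z-test
on regression slopes).  Robustness utilities cover 15-year moving windows,
lagged predictors, extra control series, and pixelwise correlation maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import xarray as xr
from scipy import stats as sps

_COND_LIMIT = 1e10


@dataclass
class PartialCorrResult:
    r: float
    p: float
    n: int
    y_name: str = "y"
    x_name: str = "x"
    controls: tuple = ()

    def __post_init__(self) -> None:
        if np.isfinite(self.r) and abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| > 1")

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass
class SubsampleDistribution:
    draws: np.ndarray
    m: int
    exhaustive: bool = False

    @property
    def n_draws(self) -> int:
        return int(self.draws.size)

    @property
    def mean(self) -> float:
        return float(np.mean(self.draws))

    @property
    def sd(self) -> float:
        return float(np.std(self.draws, ddof=1)) if self.draws.size > 1 else 0.0


@dataclass
class SensitivitySlope:
    gamma: float                # units of y per unit of the first predictor
    se: float
    p: float
    predictors: tuple = ()

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("negative standard error")


# ---------------------------------------------------------------------------
# building blocks


def detrend(values: np.ndarray, years: np.ndarray | None = None) -> np.ndarray:
    """Residuals from an OLS linear fit on year (anomalies, zero mean)."""
    y = np.asarray(values, float)
    if y.size < 4:
        raise ValueError("need at least 4 points to detrend")
    x = np.arange(y.size, dtype=float) if years is None else np.asarray(years, float)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _residualize(v: np.ndarray, controls: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(v.size), controls]) if controls.size else \
        np.ones((v.size, 1))
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_correlation(y, x, controls=(), y_name: str = "y", x_name: str = "x",
                        control_names: tuple = ()) -> PartialCorrResult:
    """Pearson correlation of y and x after removing the controls from both.

    p-value from t = r * sqrt((n - 2 - k) / (1 - r^2)) with k controls,
    two-sided.  With no controls this is the plain Pearson correlation.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    ctrl = np.column_stack([np.asarray(c, float) for c in controls]) if len(controls) \
        else np.empty((y.size, 0))
    if not (y.size == x.size and ctrl.shape[0] == y.size):
        raise ValueError("series lengths differ")
    k = ctrl.shape[1]
    n = y.size
    if n <= k + 2:
        raise ValueError("sample too small for the number of controls")
    if k:
        design = np.column_stack([np.ones(n), ctrl])
        if np.linalg.cond(design) > _COND_LIMIT:
            raise ValueError("controls are collinear (condition number too large)")
    ry = _residualize(y, ctrl)
    rx = _residualize(x, ctrl)
    denom = math.sqrt(float(ry @ ry) * float(rx @ rx))
    if denom == 0:
        raise ValueError("zero variance after removing controls")
    r = float(np.clip((ry @ rx) / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    if not control_names:
        control_names = tuple(f"c{i}" for i in range(k))
    return PartialCorrResult(r, p, n, y_name, x_name, control_names)


def subsample_partial_correlation(y, x, controls=(), m: int | None = None,
                                  n_draws: int = 1000, seed: int = 0,
                                  exhaustive_limit: int = 5000,
                                  **names) -> SubsampleDistribution:
    """Distribution of the partial correlation over m-of-n year subsamples.

    All C(n, m) subsets are enumerated when their number does not exceed
    ``exhaustive_limit``; otherwise ``n_draws`` subsets are drawn uniformly
    without replacement within each draw.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    ctrl = [np.asarray(c, float) for c in controls]
    n = y.size
    if m is None:
        m = n - 3
    if m > n:
        raise ValueError("subsample size exceeds the sample")
    if m < len(ctrl) + 4:
        raise ValueError("subsample too small for the number of controls")

    def one(idx) -> float:
        idx = np.asarray(idx)
        return partial_correlation(y[idx], x[idx], [c[idx] for c in ctrl]).r

    n_total = math.comb(n, m)
    if n_total <= exhaustive_limit:
        draws = np.array([one(list(c)) for c in combinations(range(n), m)])
        return SubsampleDistribution(draws, m, exhaustive=True)
    rng = np.random.default_rng(seed)
    draws = np.array([one(rng.choice(n, size=m, replace=False))
                      for _ in range(n_draws)])
    return SubsampleDistribution(draws, m, exhaustive=False)


def sensitivity_slope(y, predictors, predictor_names: tuple = ()) -> SensitivitySlope:
    """OLS coefficient of y on the first predictor, given the others.

    For SCD regressed on (temperature, precipitation, cloud) the returned
    slope is gamma_SCD-T in ppm per degC.
    """
    y = np.asarray(y, float)
    X = np.column_stack([np.asarray(p, float) for p in predictors])
    n, k = X.shape
    if n <= k + 2:
        raise ValueError("sample too small for the number of predictors")
    design = np.column_stack([np.ones(n), X])
    if np.linalg.cond(design) > _COND_LIMIT:
        raise ValueError("predictors are collinear (condition number too large)")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    dof = n - design.shape[1]
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se = float(np.sqrt(cov[1, 1]))
    if se == 0:
        p = 0.0 if beta[1] != 0 else 1.0
    else:
        t = beta[1] / se
        p = float(2.0 * sps.t.sf(abs(t), dof))
    if not predictor_names:
        predictor_names = tuple(f"x{i}" for i in range(k))
    return SensitivitySlope(float(beta[1]), se, p, predictor_names)


# ---------------------------------------------------------------------------
# period comparison and robustness


def compare_periods(d1, d2) -> float:
    """Two-sided p-value for a difference between periods.

    Subsample distributions are compared with a Welch two-sample t-test on
    their draws; regression slopes with a normal z-test on the coefficient
    difference using the reported standard errors.
    """
    if isinstance(d1, SensitivitySlope) and isinstance(d2, SensitivitySlope):
        se = math.hypot(d1.se, d2.se)
        if se == 0:
            return 1.0 if d1.gamma == d2.gamma else 0.0
        z = (d1.gamma - d2.gamma) / se
        return float(2.0 * sps.norm.sf(abs(z)))
    a, b = np.asarray(d1.draws, float), np.asarray(d2.draws, float)
    if np.std(a) == 0 and np.std(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


def _windowed_r(stack: np.ndarray, window: int) -> np.ndarray:
    """Windowed partial correlations for a batch of permuted series.

    ``stack`` has shape (batch, 2 + k, n): rows are y, x and k controls.
    Within each length-``window`` slice, y and x are projected onto the
    orthogonal complement of [1, t, controls] (equivalent to detrending each
    variable and partialling out the controls) and correlated.  Returns an
    array of shape (batch, n - window + 1).
    """
    from numpy.lib.stride_tricks import sliding_window_view

    batch, nvar, n = stack.shape
    win = sliding_window_view(stack, window, axis=2)  # (batch, nvar, nwin, w)
    yw = win[:, 0]
    xw = win[:, 1]
    t = np.arange(window, dtype=float)
    base = np.broadcast_to(
        np.stack([np.ones(window), t]),
        (batch, win.shape[2], 2, window))
    design = np.concatenate([base, win[:, 2:].transpose(0, 2, 1, 3)], axis=2)
    D = design.transpose(0, 1, 3, 2)                  # (batch, nwin, w, p)
    A = D.transpose(0, 1, 3, 2) @ D                   # (batch, nwin, p, p)
    rhs = np.stack([(D * yw[..., None]).sum(axis=2),
                    (D * xw[..., None]).sum(axis=2)], axis=-1)
    beta = np.linalg.solve(A, rhs)                    # (batch, nwin, p, 2)
    fitted = D @ beta                                 # (batch, nwin, w, 2)
    ry = yw - fitted[..., 0]
    rx = xw - fitted[..., 1]
    num = (ry * rx).sum(axis=-1)
    den = np.sqrt((ry * ry).sum(axis=-1) * (rx * rx).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def moving_window_correlation(y, x, controls=(), years=None, window: int = 15,
                              detrend_each: bool = True, n_perm: int = 199,
                              seed: int = 0, alternative: str = "less"):
    """Partial correlation in sliding windows plus the trend of r over time.

    Returns (list of (center_year, PartialCorrResult), slope of r on window
    center year, p-value of that slope).  Each window is detrended
    independently.

    Consecutive windows share all but one year, so the windowed correlations
    are strongly serially dependent and a naive OLS p-value on the trend is
    badly anticonservative.  The slope is therefore tested by permutation:
    the (y, x, controls) year tuples are jointly shuffled ``n_perm`` times
    (after removing each series' full-record linear trend, so that a
    stationary coupling makes the years exchangeable), and the p-value is the
    fraction of permuted slopes at least as extreme as the observed one in
    the direction of ``alternative`` ("less" for a declining r — the emerging
    negative control the diagnostic exists to detect — "greater", or
    "two-sided"), with the usual +1 correction.
    """
    if alternative not in ("less", "greater", "two-sided"):
        raise ValueError("alternative must be less, greater or two-sided")
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    ctrl = [np.asarray(c, float) for c in controls]
    n = y.size
    if years is None:
        years = np.arange(n)
    years = np.asarray(years, float)
    if n < window:
        raise ValueError("series shorter than the window")
    results = []
    for s in range(n - window + 1):
        sl = slice(s, s + window)
        yy, xx = y[sl], x[sl]
        cc = [c[sl] for c in ctrl]
        if detrend_each:
            yy, xx = detrend(yy), detrend(xx)
            cc = [detrend(c) for c in cc]
        res = partial_correlation(yy, xx, cc)
        results.append((float(np.mean(years[sl])), res))
    centers = np.array([c for c, _ in results])
    rs = np.array([res.r for _, res in results])
    slope = float(sps.linregress(centers, rs).slope)

    # permutation test of the trend in r under an exchangeable-year null
    series = np.stack([detrend(v, years) for v in (y, x, *ctrl)])
    rng = np.random.default_rng(seed)
    perms = np.stack([np.arange(n)]
                     + [rng.permutation(n) for _ in range(n_perm)])
    r_all = _windowed_r(series[:, perms].transpose(1, 0, 2), window)
    c0 = np.arange(r_all.shape[1]) - (r_all.shape[1] - 1) / 2.0
    slopes = (r_all * c0).sum(axis=1) / (c0 * c0).sum()
    obs = slopes[0]
    if alternative == "less":
        exceed = np.sum(slopes[1:] <= obs + 1e-15)
    elif alternative == "greater":
        exceed = np.sum(slopes[1:] >= obs - 1e-15)
    else:
        exceed = np.sum(np.abs(slopes[1:]) >= abs(obs) - 1e-15)
    p = float((exceed + 1) / (n_perm + 1))
    return results, slope, p


def lagged_correlation(y, x, controls=(), lag: int = 1, detrend_first: bool = True,
                       **names) -> PartialCorrResult:
    """Partial correlation of y_t with x_{t-lag} (controls contemporaneous).

    ``lag`` years are dropped from the front of y (and controls) and from the
    back of x.  With lag 0 this reduces to ``partial_correlation``.
    """
    if lag < 0:
        raise ValueError("lag must be >= 0")
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    ctrl = [np.asarray(c, float) for c in controls]
    if lag:
        y = y[lag:]
        x = x[:-lag]
        ctrl = [c[lag:] for c in ctrl]
    if detrend_first:
        y, x = detrend(y), detrend(x)
        ctrl = [detrend(c) for c in ctrl]
    return partial_correlation(y, x, ctrl, **names)


# ---------------------------------------------------------------------------
# pixelwise maps


def pixelwise_partial_correlation(field_y: xr.DataArray, field_x: xr.DataArray,
                                  control_fields=(), years=None,
                                  mask: xr.DataArray | None = None,
                                  detrend_each: bool = True) -> xr.Dataset:
    """Per-pixel detrended partial correlation over a period.

    Fields have dims (year, lat, lon); controls may also be 1-D per-year
    series applied at every pixel.  Returns a Dataset with ``r``, ``p`` and
    significance masks at P < 0.05 and P < 0.1.
    """
    if years is not None:
        years = np.asarray(years, int)
        field_y = field_y.sel(year=years)
        field_x = field_x.sel(year=years)
        control_fields = [c.sel(year=years) if isinstance(c, xr.DataArray)
                          and "year" in c.dims else c for c in control_fields]
    ny = field_y.sizes["year"]
    lat, lon = field_y["lat"].values, field_y["lon"].values
    yv = field_y.transpose("year", "lat", "lon").values.reshape(ny, -1)
    xv = field_x.transpose("year", "lat", "lon").values.reshape(ny, -1)
    cvs = []
    for c in control_fields:
        if isinstance(c, xr.DataArray) and "lat" in c.dims:
            cvs.append(c.transpose("year", "lat", "lon").values.reshape(ny, -1))
        else:
            arr = np.asarray(c, float)[:, None]
            cvs.append(np.broadcast_to(arr, (ny, yv.shape[1])))
    mvals = (mask.values.reshape(-1) if mask is not None
             else np.ones(yv.shape[1], bool))

    r = np.full(yv.shape[1], np.nan)
    p = np.full(yv.shape[1], np.nan)
    for j in range(yv.shape[1]):
        if not mvals[j]:
            continue
        yy, xx = yv[:, j], xv[:, j]
        cc = [cv[:, j] for cv in cvs]
        if not (np.all(np.isfinite(yy)) and np.all(np.isfinite(xx))):
            continue
        try:
            if detrend_each:
                yy, xx = detrend(yy), detrend(xx)
                cc = [detrend(c) for c in cc]
            res = partial_correlation(yy, xx, cc)
        except ValueError:
            continue
        r[j], p[j] = res.r, res.p

    shape = (lat.size, lon.size)
    coords = {"lat": lat, "lon": lon}
    ds = xr.Dataset(
        {
            "r": (("lat", "lon"), r.reshape(shape), {"units": "1"}),
            "p": (("lat", "lon"), p.reshape(shape), {"units": "1"}),
            "sig05": (("lat", "lon"), (p.reshape(shape) < 0.05), {"units": "1"}),
            "sig10": (("lat", "lon"), (p.reshape(shape) < 0.1), {"units": "1"}),
        },
        coords=coords,
    )
    return ds


def period_difference(map_late: xr.Dataset, map_early: xr.Dataset) -> xr.DataArray:
    """Later-minus-earlier difference of pixelwise correlation maps."""
    out = map_late["r"] - map_early["r"]
    out.attrs["units"] = "1"
    out.attrs["long_name"] = "difference in partial correlation (late - early)"
    return out
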