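import math
from itertools import combinations

import numpy as np
import pytest
import xarray as xr
from scipy import stats as sps

from scdshift import (TruthParams, compare_periods, detrend, lagged_correlation,
                      moving_window_correlation, partial_correlation,
                      pixelwise_partial_correlation, sensitivity_slope,
                      subsample_partial_correlation)
from scdshift.stats import SensitivitySlope, period_difference
from scdshift.synthetic import generate_climate_fields, generate_ndvi


class TestDetrend:
    def test_linear_series_gives_zeros(self):
        out = detrend(3.0 + 0.5 * np.arange(10))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_output_has_zero_mean(self):
        rng = np.random.default_rng(0)
        out = detrend(rng.normal(size=25))
        assert abs(out.mean()) < 1e-12

    def test_quadratic_matches_normal_equations_oracle(self):
        x = np.arange(12, dtype=float)
        y = 1 + 0.2 * x + 0.05 * x**2
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(detrend(y), y - X @ beta, atol=1e-10)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detrend(np.arange(3.0))


class TestPartialCorrelation:
    def test_no_controls_equals_pearson(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        res = partial_correlation(y, x)
        r_ref, p_ref = sps.pearsonr(y, x)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, abs=1e-10)

    def test_identical_series_r_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=15)
        z = rng.normal(size=15)
        res = partial_correlation(x, x, [z])
        assert res.r == pytest.approx(1.0)
        assert res.p == 0.0

    def test_one_control_closed_form(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=10)
        z = rng.normal(size=10)
        y = 0.6 * x + 0.4 * z + rng.normal(size=10)
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        expect = (rxy - rxz * ryz) / math.sqrt((1 - rxz**2) * (1 - ryz**2))
        res = partial_correlation(y, x, [z])
        assert res.r == pytest.approx(expect, abs=1e-12)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(17, 4)), columns=list("yxzw"))
        ours = partial_correlation(df["y"], df["x"], [df["z"], df["w"]])
        ref = pg.partial_corr(df, x="x", y="y", covar=["z", "w"])
        assert ours.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert ours.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_symmetry_in_y_and_x(self):
        rng = np.random.default_rng(5)
        y, x, z = rng.normal(size=(3, 14))
        assert partial_correlation(y, x, [z]).r == pytest.approx(
            partial_correlation(x, y, [z]).r, abs=1e-12)

    def test_collinear_controls_rejected(self):
        rng = np.random.default_rng(6)
        z = rng.normal(size=12)
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(rng.normal(size=12), rng.normal(size=12),
                                [z, 2 * z])

    def test_irrelevant_control_barely_changes_r(self):
        rng = np.random.default_rng(7)
        n = 100
        deltas = []
        for _ in range(50):
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            z = rng.normal(size=n)  # independent of both
            deltas.append(abs(partial_correlation(y, x, [z]).r
                              - partial_correlation(y, x).r))
        assert np.mean(deltas) < 2 / math.sqrt(n)

    def test_type_one_error_calibrated(self):
        """Nominal 5% test rejects ~5% of null samples (n=17, 2 controls)."""
        rng = np.random.default_rng(8)
        hits = 0
        n_sim = 2000
        for _ in range(n_sim):
            data = rng.normal(size=(4, 17))
            res = partial_correlation(data[0], data[1], [data[2], data[3]])
            hits += res.p < 0.05
        assert 0.035 <= hits / n_sim <= 0.065


class TestSubsampling:
    def test_full_sample_gives_zero_sd(self):
        rng = np.random.default_rng(9)
        y, x, z = rng.normal(size=(3, 12))
        dist = subsample_partial_correlation(y, x, [z], m=12)
        assert dist.sd == 0.0
        assert dist.mean == pytest.approx(partial_correlation(y, x, [z]).r)

    def test_exhaustive_enumeration_matches_manual(self):
        rng = np.random.default_rng(10)
        y, x = rng.normal(size=(2, 5))
        dist = subsample_partial_correlation(y, x, m=4)
        manual = []
        for idx in combinations(range(5), 4):
            idx = np.asarray(idx)
            manual.append(np.corrcoef(y[idx], x[idx])[0, 1])
        assert dist.exhaustive and dist.n_draws == 5
        np.testing.assert_allclose(np.sort(dist.draws), np.sort(manual),
                                   atol=1e-12)

    def test_17_choose_14_enumerates_680_subsets(self):
        rng = np.random.default_rng(11)
        y, x, z, w = rng.normal(size=(4, 17))
        dist = subsample_partial_correlation(y, x, [z, w], m=14)
        assert dist.exhaustive
        assert dist.n_draws == math.comb(17, 14) == 680

    def test_random_draws_deterministic_under_seed(self):
        rng = np.random.default_rng(12)
        y, x = rng.normal(size=(2, 30))
        d1 = subsample_partial_correlation(y, x, m=15, n_draws=50, seed=3,
                                           exhaustive_limit=10)
        d2 = subsample_partial_correlation(y, x, m=15, n_draws=50, seed=3,
                                           exhaustive_limit=10)
        np.testing.assert_array_equal(d1.draws, d2.draws)
        assert not d1.exhaustive

    def test_mean_converges_to_full_sample_r(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=16)
        y = 0.7 * x + rng.normal(size=16)
        full = partial_correlation(y, x).r
        errs = [abs(subsample_partial_correlation(y, x, m=m).mean - full)
                for m in (14, 15, 16)]
        assert errs[0] >= errs[1] >= errs[2]
        assert errs[2] == 0.0

    def test_too_small_subsample_rejected(self):
        rng = np.random.default_rng(14)
        y, x, z = rng.normal(size=(3, 10))
        with pytest.raises(ValueError):
            subsample_partial_correlation(y, x, [z], m=4)


class TestSensitivitySlope:
    def test_exact_linear_relation(self):
        t = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 2.0, -2.0])
        p = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0])
        c = np.array([1.0, -1.0, -1.0, 1.0, -1.0, 1.0, 1.0, -1.0])
        res = sensitivity_slope(-2.0 * t, [t, p, c])
        assert res.gamma == pytest.approx(-2.0, abs=1e-10)
        assert res.se == pytest.approx(0.0, abs=1e-8)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(15)
        t, p, c = rng.normal(size=(3, 17))
        y = -1.5 * t + 0.3 * p + rng.normal(size=17)
        res = sensitivity_slope(y, [t, p, c])
        X = sm.add_constant(np.column_stack([t, p, c]))
        fit = sm.OLS(y, X).fit()
        assert res.gamma == pytest.approx(fit.params[1], abs=1e-10)
        assert res.se == pytest.approx(fit.bse[1], abs=1e-10)
        assert res.p == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_noisy_recovery_within_three_se(self):
        rng = np.random.default_rng(16)
        t, p, c = rng.normal(size=(3, 17))
        y = -2.0 * t + rng.normal(0, 0.5, 17)
        res = sensitivity_slope(y, [t, p, c])
        assert abs(res.gamma - (-2.0)) < 3 * res.se

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(17)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            data = rng.normal(size=(4, 17))
            hits += sensitivity_slope(data[0], list(data[1:])).p < 0.05
        assert 0.03 <= hits / n_sim <= 0.07


class TestComparePeriods:
    def test_identical_degenerate_distributions(self):
        from scdshift.stats import SubsampleDistribution
        d = SubsampleDistribution(np.full(10, -0.5), m=14)
        assert compare_periods(d, d) == 1.0

    def test_separated_means_significant(self):
        from scdshift.stats import SubsampleDistribution
        rng = np.random.default_rng(18)
        d1 = SubsampleDistribution(rng.normal(-0.42, 0.09, 680), m=14)
        d2 = SubsampleDistribution(rng.normal(-0.64, 0.10, 680), m=14)
        p = compare_periods(d1, d2)
        assert p < 0.01
        # Welch oracle computed by hand
        a, b = d1.draws, d2.draws
        se = math.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        tstat = (a.mean() - b.mean()) / se
        assert abs(tstat) > 2.6

    def test_argument_order_symmetric(self):
        from scdshift.stats import SubsampleDistribution
        rng = np.random.default_rng(19)
        d1 = SubsampleDistribution(rng.normal(-0.4, 0.1, 100), m=14)
        d2 = SubsampleDistribution(rng.normal(-0.5, 0.1, 100), m=14)
        assert compare_periods(d1, d2) == pytest.approx(compare_periods(d2, d1))

    def test_slope_comparison_z_test(self):
        s1 = SensitivitySlope(-1.23, 0.76, 0.1)
        s2 = SensitivitySlope(-2.06, 0.46, 0.001)
        p = compare_periods(s1, s2)
        z = (-1.23 - (-2.06)) / math.hypot(0.76, 0.46)
        assert p == pytest.approx(2 * sps.norm.sf(abs(z)), abs=1e-12)


class TestMovingWindow:
    def test_window_count(self):
        rng = np.random.default_rng(20)
        y, x = rng.normal(size=(2, 34))
        results, _, _ = moving_window_correlation(y, x, window=15)
        assert len(results) == 34 - 15 + 1 == 20

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="window"):
            moving_window_correlation(np.arange(10.0), np.arange(10.0), window=15)

    def test_stationary_coupling_rarely_trends(self):
        rng = np.random.default_rng(21)
        hits = 0
        n = 100
        for _ in range(n):
            x = rng.normal(size=34)
            y = -0.6 * x + rng.normal(0, 1, 34)
            _, slope, p = moving_window_correlation(y, x, window=15)
            hits += p < 0.05
        assert hits / n <= 0.10

    def test_coupling_break_detected(self):
        """A coupling switching on mid-record yields a declining r."""
        rng = np.random.default_rng(22)
        hits = 0
        n = 100
        for _ in range(n):
            x = rng.normal(size=34)
            coupling = np.where(np.arange(34) < 17, 0.0, -2.0)
            y = coupling * x + rng.normal(0, 0.8, 34)
            _, slope, p = moving_window_correlation(y, x, window=15)
            hits += (slope < 0) and (p < 0.05)
        assert hits / n >= 0.80


class TestLagged:
    def test_exact_lagged_copy(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=20)
        y = np.roll(x, 1)  # y_t = x_{t-1}
        res = lagged_correlation(y[1:], x[1:], lag=1, detrend_first=False)
        # after alignment y[1+lag:] vs x[1:-lag] are identical
        assert res.r == pytest.approx(1.0)

    def test_lag_zero_reduces_to_partial_correlation(self):
        rng = np.random.default_rng(24)
        y, x, z = rng.normal(size=(3, 18))
        a = lagged_correlation(y, x, [z], lag=0, detrend_first=False)
        b = partial_correlation(y, x, [z])
        assert a.r == pytest.approx(b.r, abs=1e-12)

    def test_no_lagged_coupling_rarely_significant(self):
        rng = np.random.default_rng(25)
        hits = 0
        n = 100
        for _ in range(n):
            x = rng.normal(size=17)
            y = -2.0 * x + rng.normal(0, 0.5, 17)  # contemporaneous only
            res = lagged_correlation(y, x, lag=1)
            hits += res.p < 0.05
        assert hits / n <= 0.10


class TestPixelwise:
    @staticmethod
    def _field(values, years):
        ny, nlat, nlon = values.shape
        return xr.DataArray(values,
                            coords={"year": years,
                                    "lat": np.linspace(55, 75, nlat),
                                    "lon": np.linspace(0, 300, nlon)},
                            dims=("year", "lat", "lon"))

    def test_identical_fields_r_one(self):
        rng = np.random.default_rng(26)
        years = np.arange(1996, 2013)
        v = rng.normal(size=(17, 3, 4))
        f = self._field(v, years)
        ds = pixelwise_partial_correlation(f, f, detrend_each=False)
        np.testing.assert_allclose(ds["r"].values, 1.0, atol=1e-10)

    def test_single_pixel_matches_scalar(self):
        rng = np.random.default_rng(27)
        years = np.arange(1996, 2013)
        y = rng.normal(size=(17, 1, 1))
        x = rng.normal(size=(17, 1, 1))
        z = rng.normal(size=17)
        ds = pixelwise_partial_correlation(self._field(y, years),
                                           self._field(x, years), [z],
                                           detrend_each=False)
        ref = partial_correlation(y[:, 0, 0], x[:, 0, 0], [z])
        assert ds["r"].values.item() == pytest.approx(ref.r, abs=1e-12)
        assert ds["p"].values.item() == pytest.approx(ref.p, abs=1e-12)

    def test_sign_flip_produces_negative_difference_map(self):
        """NDVI-T coupling flipping sign across the break year shows up as a
        negative late-minus-early correlation difference nearly everywhere."""
        p = TruthParams(year_start=1982, year_end=2009, break_year=1996,
                        ndvi_beta_early=0.05, ndvi_beta_late=-0.05,
                        ndvi_noise_sd=0.003, t_pixel_noise_sd=0.8,
                        n_lat=5, n_lon=8, seed=30)
        ds = generate_climate_fields(p)
        ndvi = generate_ndvi(p, ds["tas"])
        t_sum = ds["tas"].sel(month=[7, 8]).mean("month")
        early = np.arange(1982, 1996)
        late = np.arange(1996, 2010)
        m_early = pixelwise_partial_correlation(ndvi, t_sum, years=early)
        m_late = pixelwise_partial_correlation(ndvi, t_sum, years=late)
        diff = period_difference(m_late, m_early)
        assert float((diff < 0).mean()) >= 0.9
        assert float(diff.mean()) < 0
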