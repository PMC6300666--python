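import numpy as np
import pytest

from scdshift import TruthParams, decompose, generate_co2_series
from scdshift.curvefit import CO2Series, FLAG_RETAINED
from scdshift.timeaxis import noleap_axis


def make_series(values_fn, year_start=1990, year_end=1997, calendar="noleap"):
    """Daily CO2Series from a function of (t, year, doy)."""
    t, year, doy = noleap_axis(year_start, year_end)
    conc = np.broadcast_to(np.asarray(values_fn(t, year, doy), dtype=float),
                           t.shape).copy()
    flag = np.full(t.size, FLAG_RETAINED)
    return CO2Series(t, year, doy, conc, flag, cadence="daily", calendar=calendar)


@pytest.fixture(scope="session")
def quiet_params():
    """Noise-free world: no synoptic noise, gaps, outliers or couplings."""
    return TruthParams(year_start=1990, year_end=1999, ar1_sigma=0.0,
                       gap_fraction=0.0, outlier_rate=0.0, scd_noise_sd=0.0,
                       coupling_early=0.0, coupling_late=0.0, seed=11)


@pytest.fixture(scope="session")
def lownoise_params():
    """Weak noise, strong late coupling: signal recovery fixtures."""
    return TruthParams(year_start=1979, year_end=2012, ar1_sigma=0.3,
                       gap_fraction=0.0, outlier_rate=0.0, scd_noise_sd=0.1,
                       coupling_early=0.0, coupling_late=-2.0, seed=5)


@pytest.fixture(scope="session")
def lownoise_world(lownoise_params):
    co2, truth = generate_co2_series(lownoise_params)
    return co2, truth, decompose(co2)


@pytest.fixture(scope="session")
def default_decomp():
    """Default-noise synthetic record and its decomposition."""
    params = TruthParams(seed=42)
    co2, truth = generate_co2_series(params)
    return params, co2, truth, decompose(co2)
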