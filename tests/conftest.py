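import numpy as np
import pandas as pd
import pytest

from eaakit.synthetic import (WeatherGenParams, end_to_end_fixture,
                              gen_daily_weather, gen_structured_genotypes)


def make_series(n_years=2, tmin=4.0, tmax=4.0, pcp=0.0, et0=0.0,
                start="2000-01-01"):
    """Constant daily climate series for hand-checkable index tests."""
    dates = pd.date_range(start, periods=int(365.25 * n_years) + 1, freq="D")
    return pd.DataFrame({
        "date": dates,
        "tmin": float(tmin), "tmax": float(tmax),
        "pcp": float(pcp), "et0": float(et0),
    })


@pytest.fixture(scope="session")
def constant_series():
    return make_series(n_years=2)


@pytest.fixture(scope="session")
def weather_two_sites():
    params = WeatherGenParams(n_years=12, seed=11)
    sites = pd.DataFrame({
        "id": ["low", "high"],
        "lon": [100.0, 100.0], "lat": [100.0, 100.0],
        "alt": [0.0, 1000.0],
    })
    return params, sites, gen_daily_weather(params, sites)


@pytest.fixture(scope="session")
def structured_panel():
    """4-group Balding-Nichols panel without missing data."""
    return gen_structured_genotypes(120, 1200, [30, 30, 30, 30],
                                    [0.25, 0.35, 0.2, 0.22], seed=42)


@pytest.fixture(scope="session")
def small_fixture():
    """Reduced end-to-end bundle for integration-style tests."""
    return end_to_end_fixture(7, n_acc=60, n_loci=600, n_years=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
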