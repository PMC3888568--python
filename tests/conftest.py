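import numpy as np
import pandas as pd
import pytest

from heatmort import synthdata as sd


@pytest.fixture(scope="session")
def small_counties():
    counties, demography = sd.generate_counties(12, 3, seed=7)
    return counties, demography


@pytest.fixture
def calm_params():
    """Noise-free, spell-free climate: series equal the climatology exactly."""
    return sd.ClimateParams(noise_sd=0.0, obs_noise_sd=0.0, hotspell_rate=0.0, seed=5)


def make_series(values, county="C1", start="2001-06-01", dew_offset=8.0, halfrange=5.0):
    """Single-county daily series with T_avg set to ``values``."""
    values = np.asarray(values, dtype=float)
    dates = pd.date_range(start, periods=len(values), freq="D")
    return pd.DataFrame(
        {
            "county_id": county,
            "date": dates,
            "year": dates.year,
            "tavg_c": values,
            "tmax_c": values + halfrange,
            "tmin_c": values - halfrange,
            "dewpoint_c": values - dew_offset,
        }
    )
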