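import numpy as np
import pandas as pd
import pytest

import dendropipe as dp


@pytest.fixture(scope="session")
def weather_year():
    """One deterministic year of default synthetic weather (2004)."""
    return dp.generate_weather(dp.ClimateConfig(seed=7), years=1)


@pytest.fixture(scope="session")
def stem_cfg():
    return dp.StemConfig(seed=7)


@pytest.fixture(scope="session")
def clean_stems(weather_year, stem_cfg):
    series, truth = dp.generate_stem_series(stem_cfg, weather_year)
    return series, truth


@pytest.fixture()
def flat_weather():
    """Ten days of constant, gap-free weather built by hand."""
    idx = pd.date_range("2004-06-01", periods=10 * 48, freq="30min")
    return pd.DataFrame(
        {
            "precip": 0.0, "tair": 5.0, "tsoil": 8.0, "soil_moisture": 20.0,
            "rh": 60.0, "pressure": 644.0, "solrad": 0.2,
            "wind_speed": 10.0, "wind_gust": 15.0,
        },
        index=pd.DatetimeIndex(idx, name="timestamp"),
    )
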