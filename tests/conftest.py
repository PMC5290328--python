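import numpy as np
import pytest

from drylandsim.synthetic_data import (WeatherGenParams, apply_monthly_normals,
                                       gen_daily_weather, gen_soil_profile)
from drylandsim.vegetation import build_vegetation


@pytest.fixture(scope="session")
def profile():
    return gen_soil_profile(sand=0.4, clay=0.2, total_depth=100)


@pytest.fixture(scope="session")
def dryland_weather():
    """Three years of synthetic dryland forcing (MAT 8 degC, MAP 300 mm)."""
    params = WeatherGenParams(mat_target=8.0, map_target=300.0,
                              temp_seasonal_amplitude=15.0,
                              precip_seasonality=0.35, years=3, seed=42)
    return gen_daily_weather(params)


@pytest.fixture(scope="session")
def vegetation(dryland_weather, profile):
    return build_vegetation(apply_monthly_normals(dryland_weather), profile)


@pytest.fixture(scope="session")
def monthly_atmos():
    return (np.full(12, 55.0), np.full(12, 2.5), np.full(12, 0.4))


@pytest.fixture(scope="session")
def sim_result(dryland_weather, profile, vegetation, monthly_atmos):
    from drylandsim.water_balance import simulate
    rh, wind, cloud = monthly_atmos
    return simulate(dryland_weather, profile, vegetation, 40.0, rh, wind, cloud)
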