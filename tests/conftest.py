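import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from soilnflux import SimConfig

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    """One simulated year at full chamber density, fixed seed."""
    return SimConfig(seed=11, n_years=1)


@pytest.fixture(scope="session")
def small_climate(small_config):
    from soilnflux import simulate_climate
    return simulate_climate(small_config)


@pytest.fixture(scope="session")
def small_daily(small_config, small_climate):
    from soilnflux import daily_aggregate, simulate_flux_records
    records = simulate_flux_records(small_config, small_climate)
    return daily_aggregate(records)


def constant_daily(value=10.0, n_days=365, start="2019-01-01",
                   species="NO", treatment="control"):
    """A constant daily-flux frame for integration arithmetic."""
    dates = pd.date_range(start, periods=n_days, freq="D")
    return pd.DataFrame({
        "date": dates, "treatment": treatment, "species": species,
        "mean_flux": float(value), "se": np.nan,
        "n_fluxes": 1, "n_chambers": 1,
    })
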