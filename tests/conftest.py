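import numpy as np
import pandas as pd
import pytest

import profitmax as pm


@pytest.fixture(scope="session")
def registry():
    return pm.load_species_registry()


@pytest.fixture(scope="session")
def blakelyi(registry):
    return registry["E. blakelyi"]


@pytest.fixture
def simple_curve():
    return pm.VulnerabilityCurve(b=2.0, c=2.0, k_max=1.5)


@pytest.fixture
def midday_env():
    return pm.LeafEnvironment(
        T_air=28.0, PAR_leaf=1500.0, Cs=400.0, VPD_leaf=2.0
    )


@pytest.fixture
def wet_soil():
    return pm.default_profile(theta_frac=0.9)


@pytest.fixture(scope="session")
def short_forcing():
    """90 days of rain-free, hot and dry 3-hourly weather."""
    spec = pm.ClimateSpec(map_mm_yr=600.0, t_mean=24.0)
    f = pm.generate_forcing(spec, years=1, seed=42)
    f = f.iloc[: 90 * 8].copy()
    f["precip"] = 0.0
    return f
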