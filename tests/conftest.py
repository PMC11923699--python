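import numpy as np
import pytest

import geofalter as gf
from geofalter.synthetic import CovariateSpec


@pytest.fixture(scope="session")
def small_survey():
    """A compact synthetic survey reused by read-only tests."""
    cfg = gf.SimulationConfig(
        n_clusters=25,
        individuals_per_cluster=(3, 6),
        domain_extent=(0.0, 200.0, 0.0, 200.0),
        grid_cell_km=20.0,
        n_months=24,
        seed=11,
    )
    return gf.simulate_survey(cfg)


@pytest.fixture()
def haz_params():
    """Truth near the fitted height-for-age values."""
    return gf.GeoModelParams(
        alpha=-1.23, beta=np.array([0.06]), sigma2=0.15, phi=18.28, omega2=2.02
    )


@pytest.fixture()
def spei_only_config(haz_params):
    """Single SPEI-like covariate acting at lag 3 with coefficient 0.06."""
    return gf.SimulationConfig(
        n_clusters=300,
        individuals_per_cluster=(10, 10),
        true_params=haz_params,
        covariate_specs=(
            CovariateSpec(
                "spei",
                "monthly",
                spatial_range_km=80.0,
                marginal_sd=1.0,
                seasonal_amplitude=0.3,
            ),
        ),
        true_lags={"spei": 3},
    )
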