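import numpy as np
import pandas as pd
import pytest

from rainmob import DGPSpec, gen_outcome, gen_rain_grid, gen_survey
from rainmob.experiments import simulate_panel


@pytest.fixture(scope="session")
def small_grid():
    """31-year 4x4 grid with seasonality, year anomalies and day noise."""
    return gen_rain_grid(11, n_years=31, n_cells_x=4, n_cells_y=4)


@pytest.fixture(scope="session")
def tiny_survey(small_grid):
    """2 countries x 3 sites x 10 respondents, full covariate schema."""
    dgp = DGPSpec(seed=12, n_countries=2, sites_per_country=3, respondents_per_site=10)
    sites, respondents = gen_survey(dgp, small_grid)
    return dgp, sites, respondents


@pytest.fixture(scope="session")
def ushape_panel():
    """Medium U-shaped panel with site heterogeneity, for model/margin tests."""
    dgp = DGPSpec(
        seed=21,
        n_countries=4,
        sites_per_country=50,
        respondents_per_site=60,
        ushape_gamma=0.6,
        site_sd=0.3,
    )
    return dgp, simulate_panel(dgp)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
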