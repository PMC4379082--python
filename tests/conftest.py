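import numpy as np
import pandas as pd
import pytest

from uhtape import GrowthModelParams, simulate_phase1, weekly_percentiles


@pytest.fixture(scope="session")
def default_params():
    return GrowthModelParams()


@pytest.fixture(scope="session")
def phase1_default(default_params):
    """Moderate-size paired cohort under default growth parameters."""
    return simulate_phase1(default_params, n_per_week=200, seed=123)


@pytest.fixture(scope="session")
def default_chart(phase1_default):
    return weekly_percentiles(phase1_default, site="synthetic")


@pytest.fixture()
def flat_chart():
    """Noise-free chart: all percentiles on the line 1.0 + 0.9 * week."""
    weeks = np.arange(24, 37)
    uh = 1.0 + 0.9 * weeks
    table = pd.DataFrame(
        {
            "week": weeks,
            "n": 10,
            "mean_cm": uh,
            "sd_cm": 0.0,
            "p10_cm": uh,
            "p50_cm": uh,
            "p90_cm": uh,
        }
    )
    return table
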