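import numpy as np
import pytest

from atrophy_forecast import blme
from atrophy_forecast.cohort import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort on a desk-scale grid, shared across tests."""
    cfg = CohortConfig(n_controls=30, n_carriers=40, grid_shape=(8, 8, 8),
                       seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_control_model(small_cohort):
    return blme.fit_control_model(small_cohort, mode="pooled")


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Exactly linear trajectories: no noise, no random effects."""
    cfg = CohortConfig(
        n_controls=6, n_carriers=4, grid_shape=(7, 7, 7), seed=5,
        baseline_volume_sd=0.0, control_slope_sd=0.0, residual_noise_sd=0.0,
        acceleration_magnitude=0.0, scan_interval_jitter_sd=0.0,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
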