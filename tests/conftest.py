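import numpy as np
import pandas as pd
import pytest

from airdlm import SimConfig, simulate_panel
from airdlm.config import POLLUTANTS

TRUE_RR10 = 1.03  # rate ratio per 10 units used by recovery studies
BETA_UNIT = float(np.log(TRUE_RR10) / 10.0)


def quiet_config(**kwargs) -> SimConfig:
    """Generator config with all systematic structure switched off."""
    defaults = dict(
        lag_log_rr=(0.0,) * 8,
        weather_effect={"temperature": 0.0, "humidity": 0.0},
        seasonal_amplitudes={k: (0.0, 0.0) for k in
                             POLLUTANTS + ["temperature", "humidity", "admissions"]},
        overdispersion=1.0,
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def default_panel():
    """One seeded study-sized panel with a lag-0 effect, reused read-only."""
    cfg = SimConfig(n_days=800, seed=11, lag_log_rr=(BETA_UNIT, 0, 0, 0, 0, 0, 0, 0))
    panel, truth = simulate_panel(cfg)
    return panel, truth, cfg


@pytest.fixture
def small_panel():
    cfg = SimConfig(n_days=240, seed=5)
    panel, _ = simulate_panel(cfg)
    return panel, cfg


def make_glm_fixture(seed: int, n: int = 30, p: int = 3):
    """Small Poisson regression fixture with a well-conditioned design."""
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(p - 1)])
    beta = rng.normal(scale=0.3, size=p)
    beta[0] = 1.0
    y = rng.poisson(np.exp(X @ beta))
    return y, X
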