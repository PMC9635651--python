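import numpy as np
import pandas as pd
import pytest

from metml.synthetic import (
    SimulationConfig,
    g2f_like_config,
    rice_like_config,
    simulate_met_data,
    G2F_DROPPED_ENVS,
)


@pytest.fixture(scope="session")
def small_met():
    """30 genotypes x 4 environments with mixed genetic/environmental signal."""
    cfg = SimulationConfig(
        n_genotypes=30, p_markers=80,
        years=(2014, 2015), locations=("Ames", "Lincoln"),
        v_g=0.4, v_w=0.25, v_gw=0.1, v_e=0.25, seed=101,
    )
    met, truth = simulate_met_data(cfg)
    return met, truth


@pytest.fixture(scope="session")
def g2f_met():
    """Maize-network shape: 6 locations x 4 years = 22 environments."""
    met, truth = simulate_met_data(
        g2f_like_config(seed=202, n_genotypes=40, p_markers=80),
        drop_env_ids=G2F_DROPPED_ENVS,
    )
    return met, truth


@pytest.fixture(scope="session")
def rice_met():
    """Rice-series shape: 320 lines, one location, years 2009-2013, ECs provided."""
    met, truth = simulate_met_data(
        rice_like_config(seed=303, p_markers=60), compute_ecs=False
    )
    return met, truth


@pytest.fixture()
def toy_weather():
    """Deterministic 20-day single-environment weather table for exact checks."""
    dates = pd.date_range("2020-05-01", periods=20, freq="D")
    rng = np.random.default_rng(7)
    tmin = np.round(rng.uniform(8, 15, 20), 1)
    tmax = tmin + np.round(rng.uniform(5, 12, 20), 1)
    precip = np.round(np.where(rng.random(20) < 0.4, rng.gamma(2, 6, 20), 0.0), 1)
    return pd.DataFrame(
        {
            "env_id": "Toy_2020",
            "date": dates,
            "tmin": tmin,
            "tmax": tmax,
            "tmean": np.round((tmin + tmax) / 2, 2),
            "precipitation": precip,
            "solar_radiation": np.round(rng.uniform(10, 28, 20), 1),
            "wind_speed_2m": np.round(rng.uniform(0.5, 5, 20), 2),
            "relative_humidity": np.round(rng.uniform(40, 90, 20), 1),
        }
    )
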