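import datetime as dt

import numpy as np
import pandas as pd
import pytest

from heatvuln import SimConfig
from heatvuln.exposure import ExposureLookup
from heatvuln.synthetic import (
    generate_adjacency,
    generate_events,
    generate_sdoh,
    generate_weather,
)


@pytest.fixture(scope="session")
def small_sim():
    """One warm season, 3x3 county lattice, moderate event rate."""
    cfg = SimConfig(
        n_rows=3, n_cols=3, years=(2010,), baseline_rate=2.0,
        gamma={}, gamma0=0.05, beta_noise_sd=0.0, duplicate_fraction=0.05, seed=11,
    )
    weather = generate_weather(cfg)
    sdoh = generate_sdoh(cfg)
    W = generate_adjacency(cfg.n_rows, cfg.n_cols)
    events, truth = generate_events(cfg, weather, sdoh, W)
    return cfg, weather, sdoh, W, events, truth


def exposure_from_weather(weather: pd.DataFrame) -> pd.DataFrame:
    """County exposure table with himax stubbed as tmax (HI tested separately)."""
    return weather.assign(himax_c=weather["tmax_c"])[
        ["county_id", "date", "tmax_c", "tmean_c", "tmin_c", "himax_c"]
    ]


@pytest.fixture(scope="session")
def small_lookup(small_sim):
    _, weather, *_ = small_sim
    return ExposureLookup.from_series(exposure_from_weather(weather))


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)


def season_2010():
    return (dt.date(2010, 5, 1), dt.date(2010, 9, 30))
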