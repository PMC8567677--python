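"""Synthetic study inputs with known ground truth.

The restricted inputs of a county-level heat-morbidity study (individual
health events, daily weather, census covariates, county geography) are
emulated here so every downstream stage is testable without any download:

* warm-season daily temperature series with a seasonal cycle, county
  offsets, and AR(1) day-to-day autocorrelation;
* a correlated county covariate table (some pairs planted above |r| = 0.7
  to exercise collinearity pruning);
* a rectangular-lattice county map with queen contiguity;
* Poisson-thinned health events whose county log odds ratio per deg C is a
  known linear function of the covariates, optionally with spatially
  autocorrelated noise.

The generative model is chosen so the estimand is exact: with daily counts
``Poisson(baseline * exp(beta_c * (T - Tbar_c)))`` the case-crossover odds
ratio per deg C equals ``exp(beta_c)``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import DEDUP_WINDOWS, SimConfig, stage_seed

__all__ = [
    "GroundTruth",
    "generate_weather",
    "generate_sdoh",
    "generate_adjacency",
    "generate_events",
    "generate_all",
]

#: Representative ICD-9 code emitted for each outcome class.
_OUTCOME_ICD9 = {
    "cardiovascular": "410.9",
    "dehydration": "276.51",
    "heat_related": "992.0",
    "acute_renal": "584.9",
    "respiratory": "480.9",
}


@dataclass
class GroundTruth:
    """Planted parameters, kept alongside the generated data for recovery tests."""

    county_beta: pd.Series          # county -> true log-OR per deg C (incl. noise)
    county_beta_linear: pd.Series   # noise-free part gamma0 + gamma . sdoh_c
    gamma: Mapping[str, float]
    gamma0: float
    sdoh_table: pd.DataFrame


def _season_frame(config: SimConfig) -> pd.DataFrame:
    """One row per in-season day with year index and within-season position."""
    rows = []
    for year in config.years:
        days = config.season.dates(year)
        n = len(days)
        for i, d in enumerate(days):
            rows.append((d, year, i, n))
    df = pd.DataFrame(rows, columns=["date", "year", "day_of_season", "season_length"])
    return df


def generate_weather(config: SimConfig) -> pd.DataFrame:
    """Daily county weather: tmax/tmean/tmin (deg C) and RH (%).

    tmean = seasonal half-sine peaking mid-season + county offset + AR(1)
    noise (restarted each season); tmax/tmin sit a noisy diurnal half-range
    above/below tmean; humidity is clipped to [5, 100].
    """
    rng = np.random.default_rng(stage_seed(config.seed, "weather"))
    cal = _season_frame(config)
    n_days = len(cal)
    n = config.n_counties
    if n_days == 0:
        raise ValueError("no in-season days; check years/season")

    frac = cal["day_of_season"].to_numpy() / np.maximum(cal["season_length"].to_numpy() - 1, 1)
    seasonal = config.t_base + config.t_amplitude * np.sin(np.pi * frac)

    offsets = rng.normal(0.0, config.county_offset_sd, size=n) if config.county_offset_sd else np.zeros(n)
    noise = np.zeros((n, n_days))
    if config.ar_sd > 0:
        innov = rng.normal(0.0, config.ar_sd, size=(n, n_days))
        # AR(1) restarted at each season start so lags never straddle years
        for year in config.years:
            sel = (cal["year"] == year).to_numpy()
            noise[:, sel] = lfilter([1.0], [1.0, -config.ar_phi], innov[:, sel], axis=1)

    tmean = seasonal[None, :] + offsets[:, None] + noise
    half_hi = 4.0 + (rng.normal(0.0, config.daily_range_sd, size=(n, n_days))
                     if config.daily_range_sd else 0.0)
    half_lo = 4.5 + (rng.normal(0.0, config.daily_range_sd, size=(n, n_days))
                     if config.daily_range_sd else 0.0)
    tmax = tmean + np.abs(half_hi)
    tmin = tmean - np.abs(half_lo)
    rh_noise = (
        rng.normal(0.0, config.rh_sd, size=(n, n_days)) if config.rh_sd else np.zeros((n, n_days))
    )
    rh = np.clip(config.rh_mean + rh_noise, 5.0, 100.0)

    ids = config.county_ids
    out = pd.DataFrame(
        {
            "county_id": np.repeat(ids, n_days),
            "date": np.tile(cal["date"].to_numpy(), n),
            "tmean_c": tmean.ravel(),
            "tmax_c": tmax.ravel(),
            "tmin_c": tmin.ravel(),
            "rh_pct": rh.ravel(),
        }
    )
    return out[["county_id", "date", "tmax_c", "tmean_c", "tmin_c", "rh_pct"]]


def generate_sdoh(config: SimConfig) -> pd.DataFrame:
    """County covariate table drawn from the configured multivariate normal."""
    if config.n_counties < 2:
        raise ValueError("need at least 2 counties for a covariate table")
    spec = config.sdoh
    rng = np.random.default_rng(stage_seed(config.seed, "sdoh"))
    corr = spec.corr_matrix
    eigval, eigvec = np.linalg.eigh(corr)
    if eigval.min() < -1e-10:
        raise ValueError("requested correlation matrix is not positive semi-definite")
    factor = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    z = rng.standard_normal((config.n_counties, len(spec.names)))
    x = z @ factor.T
    means = np.asarray(spec.means)
    sds = np.asarray(spec.sds)
    values = np.clip(means + sds * x, np.asarray(spec.lower), np.asarray(spec.upper))
    table = pd.DataFrame(values, columns=list(spec.names))
    table.insert(0, "county_id", config.county_ids)
    return table


def generate_adjacency(n_rows: int, n_cols: int) -> np.ndarray:
    """Binary symmetric queen-contiguity adjacency of an n_rows x n_cols lattice.

    Interior cells have 8 neighbours, edges 5, corners 3.
    """
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("lattice dimensions must be positive")
    n = n_rows * n_cols
    W = np.zeros((n, n), dtype=np.int8)
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < n_rows and 0 <= cc < n_cols:
                        W[i, rr * n_cols + cc] = 1
    return W


def plant_county_betas(
    config: SimConfig, sdoh: pd.DataFrame, adjacency: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(county_beta, noise-free linear part) of the planted log-OR surface.

    Noise is iid normal, optionally filtered through the simultaneous
    autoregressive operator ``(I - rho * W_rownorm)^-1`` so the planted
    surface matches the spatial-lag family fitted in stage 2.
    """
    n = config.n_counties
    linear = np.full(n, config.gamma0, dtype=float)
    for name, g in config.gamma.items():
        linear = linear + g * sdoh[name].to_numpy(dtype=float)
    eps = rng.normal(0.0, config.beta_noise_sd, size=n) if config.beta_noise_sd > 0 else np.zeros(n)
    if config.spatial_rho > 0 and eps.any():
        rowsum = adjacency.sum(axis=1).astype(float)
        rowsum[rowsum == 0] = 1.0
        w_row = adjacency / rowsum[:, None]
        eps = np.linalg.solve(np.eye(n) - config.spatial_rho * w_row, eps)
    return linear + eps, linear


def generate_events(
    config: SimConfig,
    weather: pd.DataFrame,
    sdoh: pd.DataFrame,
    adjacency: np.ndarray,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Raw event table plus the planted ground truth.

    Daily county counts are Poisson with rate
    ``baseline_rate * exp(beta_c * (tmean - mean tmean of the county))``;
    each event becomes a row with a masked integer patient id.  A
    ``duplicate_fraction`` of patients receive a second visit 1 to
    (window - 1) days later to exercise deduplication.
    """
    if config.baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive to generate events")
    ids = config.county_ids
    missing = set(ids) - set(weather["county_id"].unique())
    if missing:
        raise ValueError(f"weather does not cover counties: {sorted(missing)[:5]}")

    rng = np.random.default_rng(stage_seed(config.seed, "events"))
    beta, linear = plant_county_betas(config, sdoh, adjacency, rng)

    w = weather.sort_values(["county_id", "date"])
    pivot = w.pivot(index="county_id", columns="date", values="tmean_c").loc[ids]
    t = pivot.to_numpy(dtype=float)
    anomaly = t - t.mean(axis=1, keepdims=True)
    lam = config.baseline_rate * np.exp(beta[:, None] * anomaly)
    counts = rng.poisson(lam)

    county_rep = np.repeat(np.arange(len(ids)), counts.sum(axis=1))
    date_cols = np.asarray(pivot.columns)
    date_rep = np.concatenate([np.repeat(date_cols, counts[i]) for i in range(len(ids))]) \
        if counts.sum() else np.asarray([], dtype=object)

    n_events = len(county_rep)
    patient_id = np.arange(1, n_events + 1, dtype=np.int64)
    events = pd.DataFrame(
        {
            "patient_id": patient_id,
            "date": date_rep,
            "icd9": _OUTCOME_ICD9[config.outcome],
            "stream": config.stream,
            "county_id": np.asarray(ids, dtype=object)[county_rep],
            "zip_id": ["Z" + ids[i] for i in county_rep],
        }
    )

    if config.duplicate_fraction > 0 and n_events:
        window = DEDUP_WINDOWS[config.outcome]
        n_dup = int(round(config.duplicate_fraction * n_events))
        pick = rng.choice(n_events, size=n_dup, replace=False)
        lags = rng.integers(1, max(window, 2), size=n_dup)
        dup = events.iloc[pick].copy()
        dup["date"] = [d + _dt.timedelta(days=int(k)) for d, k in zip(dup["date"], lags)]
        in_season = [config.season.contains(d) for d in dup["date"]]
        dup = dup[np.asarray(in_season)]
        events = pd.concat([events, dup], ignore_index=True)

    events = events.sort_values(["county_id", "date", "patient_id"], ignore_index=True)
    truth = GroundTruth(
        county_beta=pd.Series(beta, index=ids, name="county_beta"),
        county_beta_linear=pd.Series(linear, index=ids, name="county_beta_linear"),
        gamma=dict(config.gamma),
        gamma0=config.gamma0,
        sdoh_table=sdoh,
    )
    return events, truth


def generate_all(config: SimConfig):
    """Convenience: weather, sdoh, adjacency, events, truth in one call."""
    weather = generate_weather(config)
    sdoh = generate_sdoh(config)
    adjacency = generate_adjacency(config.n_rows, config.n_cols)
    events, truth = generate_events(config, weather, sdoh, adjacency)
    return weather, sdoh, adjacency, events, truth
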