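"""Calibration and parameter-recovery experiments.

Self-contained simulation studies used to validate the two-stage method
against the generator's planted truth: stage-1 log-OR recovery, type-I
error of the county Wald test under the null, stage-2 recovery of planted
covariate effects, and spatial-lag rho recovery.  Each function seeds all
randomness from a single integer and reports summary numbers; they back
both the validation test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .case_crossover import build_strata, conditional_logistic_fit, deduplicate_events
from .config import SDOHSpec, SimConfig
from .exposure import ExposureLookup
from .spatial import spatial_lag_fit, stage2_analysis
from .synthetic import generate_adjacency, generate_events, generate_sdoh, generate_weather

__all__ = [
    "stage1_recovery",
    "null_calibration",
    "stage2_recovery",
    "rho_recovery",
    "fit_generated_county",
]


def _exposure_table(weather: pd.DataFrame) -> pd.DataFrame:
    # tmean drives event generation; himax is irrelevant here, stub with tmax
    return weather.assign(himax_c=weather["tmax_c"])[
        ["county_id", "date", "tmax_c", "tmean_c", "tmin_c", "himax_c"]
    ]


def fit_generated_county(config: SimConfig, county: str = "C001", metric: str = "tmean",
                         lag: int = 0):
    """Generate one synthetic study and fit one county's log-OR."""
    weather = generate_weather(config)
    sdoh = generate_sdoh(config)
    W = generate_adjacency(config.n_rows, config.n_cols)
    events, truth = generate_events(config, weather, sdoh, W)
    events = events.assign(outcome=config.outcome)
    events = deduplicate_events(events)
    lookup = ExposureLookup.from_series(_exposure_table(weather))
    strata = build_strata(
        events[events["county_id"] == county], lookup, metric, lag,
        seed=config.seed, season=config.season,
    )
    return conditional_logistic_fit(strata), truth


@dataclass
class RecoveryResult:
    n_replicates: int
    n_within_3se: int
    estimates: np.ndarray
    ses: np.ndarray

    @property
    def fraction_within_3se(self) -> float:
        return self.n_within_3se / self.n_replicates


def stage1_recovery(
    n_replicates: int = 100,
    gamma0: float = 0.05,
    baseline_rate: float = 36.0,
    seed: int = 0,
) -> RecoveryResult:
    """Replicated single-county recovery of a planted log-OR per deg C.

    Each replicate simulates one warm season at a daily event rate high
    enough for ~5,000 analyzed cases, fits the conditional logistic model
    at lag-0 mean temperature, and checks |beta-hat - gamma0| <= 3 SE.
    """
    est = np.empty(n_replicates)
    ses = np.empty(n_replicates)
    hits = 0
    for rep in range(n_replicates):
        cfg = SimConfig(
            n_rows=1, n_cols=2, years=(2010,), baseline_rate=baseline_rate,
            gamma={}, gamma0=gamma0, beta_noise_sd=0.0, duplicate_fraction=0.05,
            seed=(seed * 100003 + rep) % (2**31),
        )
        fit, _ = fit_generated_county(cfg)
        est[rep], ses[rep] = fit.beta, fit.se
        hits += abs(fit.beta - gamma0) <= 3 * fit.se
    return RecoveryResult(n_replicates, hits, est, ses)


def null_calibration(
    n_rows: int = 20,
    n_cols: int = 25,
    baseline_rate: float = 1.0,
    alpha_z: float = 1.96,
    seed: int = 0,
) -> dict:
    """Type-I error of the county-level Wald test under a null simulation.

    With beta = 0 planted everywhere, the fraction of counties where
    |beta-hat / SE| > 1.96 should sit near 5 %.
    """
    cfg = SimConfig(
        n_rows=n_rows, n_cols=n_cols, years=(2010,), baseline_rate=baseline_rate,
        gamma={}, gamma0=0.0, beta_noise_sd=0.0, duplicate_fraction=0.0,
        seed=seed % (2**31),
    )
    weather = generate_weather(cfg)
    sdoh = generate_sdoh(cfg)
    W = generate_adjacency(cfg.n_rows, cfg.n_cols)
    events, _ = generate_events(cfg, weather, sdoh, W)
    events = events.assign(outcome=cfg.outcome)
    lookup = ExposureLookup.from_series(_exposure_table(weather))
    strata = build_strata(events, lookup, "tmean", 0, seed=seed, season=cfg.season)

    order = np.argsort(strata.county_ids, kind="mergesort")
    cids = strata.county_ids[order]
    x = strata.exposures[order]
    bounds = np.flatnonzero(np.r_[True, cids[1:] != cids[:-1], True])
    rejections = 0
    n_fitted = 0
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 30:
            continue
        fit = conditional_logistic_fit(x[a:b])
        n_fitted += 1
        rejections += abs(fit.beta / fit.se) > alpha_z
    return {
        "n_counties": n_fitted,
        "n_rejections": rejections,
        "rejection_rate": rejections / n_fitted if n_fitted else np.nan,
    }


def _recovery_sdoh_spec() -> SDOHSpec:
    """Six independent standardized covariates for planted-effect recovery."""
    k = 6
    return SDOHSpec(
        names=tuple(f"v{i + 1}" for i in range(k)),
        means=(0.0,) * k,
        sds=(1.0,) * k,
        corr=tuple(tuple(float(i == j) for j in range(k)) for i in range(k)),
        lower=(-np.inf,) * k,
        upper=(np.inf,) * k,
    )


def stage2_recovery(
    n_replicates: int = 50,
    n_rows: int = 10,
    n_cols: int = 10,
    baseline_rate: float = 15.0,
    gamma: dict | None = None,
    gamma0: float = 0.02,
    beta_noise_sd: float = 0.005,
    spatial_rho: float = 0.0,
    n_permutations: int = 199,
    seed: int = 0,
) -> dict:
    """End-to-end recovery of planted covariate effects on county log-ORs.

    Each replicate simulates 100 counties at ~2,000 analyzed cases per
    county, runs stage 1 per county and the full stage-2 chain
    (prune -> stepwise -> aspatial/spatial choice), then checks that both
    planted variables are retained with the correct sign and that each
    coefficient falls within 3 SE of its planted value (the dependent
    variable is the OR, so the target is gamma to first order in beta).
    """
    gamma = {"v1": 0.01, "v2": -0.01} if gamma is None else gamma
    spec = _recovery_sdoh_spec()
    both_signs = 0
    within_3se = 0
    coef_records = []
    for rep in range(n_replicates):
        cfg = SimConfig(
            n_rows=n_rows, n_cols=n_cols, years=(2010,), baseline_rate=baseline_rate,
            gamma=gamma, gamma0=gamma0, beta_noise_sd=beta_noise_sd,
            spatial_rho=spatial_rho, duplicate_fraction=0.0, sdoh=spec,
            seed=(seed * 99991 + rep) % (2**31),
        )
        weather = generate_weather(cfg)
        sdoh = generate_sdoh(cfg)
        W = generate_adjacency(cfg.n_rows, cfg.n_cols)
        events, truth = generate_events(cfg, weather, sdoh, W)
        events = events.assign(outcome=cfg.outcome)
        lookup = ExposureLookup.from_series(_exposure_table(weather))
        strata = build_strata(events, lookup, "tmean", 0, seed=cfg.seed, season=cfg.season)

        order = np.argsort(strata.county_ids, kind="mergesort")
        cids = strata.county_ids[order]
        x = strata.exposures[order]
        bound = np.flatnonzero(np.r_[True, cids[1:] != cids[:-1], True])
        rows = []
        for a, b in zip(bound[:-1], bound[1:]):
            fit = conditional_logistic_fit(x[a:b])
            rows.append((cids[a], fit.beta, fit.se, fit.or_value, b - a, fit.aic,
                         fit.converged))
        ors = pd.DataFrame(
            rows, columns=["county_id", "beta", "se", "or", "n_cases", "aic", "converged"]
        )
        ors.insert(1, "outcome", cfg.outcome)
        ors.insert(2, "stream", cfg.stream)
        ors.insert(3, "metric", "tmean")
        ors.insert(4, "lag", 0)

        (res,) = stage2_analysis(
            ors, sdoh, W.astype(float), list(sdoh["county_id"]),
            n_permutations=n_permutations, seed=cfg.seed,
        )
        coefs = res.coefficients
        ok_signs = all(
            name in coefs.index and np.sign(coefs[name]) == np.sign(g)
            for name, g in gamma.items()
        )
        both_signs += ok_signs
        # 3-SE check on the aspatial coefficient scale (spatial-lag total
        # impacts at small rho differ from beta by O(rho), well inside 3 SE)
        se_lookup = _ols_se_for(res, ors, sdoh)
        ok_3se = all(
            name in coefs.index
            and abs(coefs[name] - g) <= 3 * se_lookup.get(name, np.inf)
            for name, g in gamma.items()
        )
        within_3se += ok_3se
        coef_records.append({name: coefs.get(name, np.nan) for name in gamma})
    return {
        "n_replicates": n_replicates,
        "sign_recovery_rate": both_signs / n_replicates,
        "within_3se_rate": within_3se / n_replicates,
        "mean_coefficients": pd.DataFrame(coef_records).mean().to_dict(),
        "planted": dict(gamma),
    }


def _ols_se_for(res, ors: pd.DataFrame, sdoh: pd.DataFrame) -> dict:
    """Aspatial standard errors for the selected variables (recovery metric)."""
    from .spatial import ols_fit

    merged = ors.merge(sdoh, on="county_id")
    X = merged[list(res.selected_variables)]
    sel = [v for v in res.coefficients.index if v in X.columns]
    fit = ols_fit(merged["or"].to_numpy(), X[sel])
    return fit.se.to_dict()


def rho_recovery(
    rho: float = 0.1,
    n_rows: int = 7,
    n_cols: int = 7,
    seed: int = 0,
) -> dict:
    """Spatial-lag rho recovery on a queen lattice.

    Simulates y = (I - rho W)^-1 (X beta + eps) with binary (not
    row-standardized) weights and refits by maximum likelihood; rho = 0.1
    sits safely inside the feasible interval (~(-0.29, 0.17) for 7x7).
    """
    rng = np.random.default_rng(seed % (2**31))
    W = generate_adjacency(n_rows, n_cols).astype(float)
    n = n_rows * n_cols
    X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["u", "v"])
    eta = 1.0 + 0.5 * X["u"].to_numpy() - 0.8 * X["v"].to_numpy() + rng.normal(0, 0.5, n)
    y = np.linalg.solve(np.eye(n) - rho * W, eta)
    fit = spatial_lag_fit(y, X, W)
    return {
        "rho_true": rho,
        "rho_hat": fit.rho,
        "rho_se": fit.rho_se,
        "within_3se": bool(abs(fit.rho - rho) <= 3 * fit.rho_se),
        "converged": fit.converged,
    }
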