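"""End-to-end orchestration: simulate -> exposure -> case-crossover -> spatial.

Each stage reads and writes plain CSV/JSON artifacts in ``config.workdir``
and contributes counts to a run report, so every filter (deduplication,
missing-exposure stratum drops, the <min_cases county gate, collinearity
pruning, stepwise selection, model choice) is accounted for and the whole
run is reproducible from (config, seed).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import io as hio
from .case_crossover import (
    build_strata,
    classify_outcome,
    deduplicate_events,
    estimate_county_ors,
    select_best_metric_lag,
)
from .config import RunConfig, stage_seed
from .exposure import ExposureLookup, c_to_f, f_to_c, heat_index, validate_exposure
from .spatial import stage2_analysis
from .synthetic import generate_adjacency, generate_events, generate_sdoh, generate_weather

logger = logging.getLogger(__name__)

__all__ = ["run_simulate", "run_exposure", "run_casecrossover", "run_spatial", "run_pipeline"]


def _paths(config: RunConfig) -> dict[str, Path]:
    root = Path(config.workdir)
    return {
        "root": root,
        "weather": root / "weather.csv",
        "sdoh": root / "sdoh.csv",
        "adjacency": root / "adjacency.csv",
        "events": root / "events.csv",
        "truth": root / "truth.json",
        "exposure": root / "exposure.csv",
        "county_or": root / "county_or.csv",
        "aic_grid": root / "aic_grid.csv",
        "stage2": root / "stage2.csv",
        "report": root / "report.json",
    }


def run_simulate(config: RunConfig) -> dict:
    """Generate weather, SDOH, adjacency, events and truth; write artifacts."""
    p = _paths(config)
    p["root"].mkdir(parents=True, exist_ok=True)
    sim = config.sim.with_(seed=config.seed)
    weather = generate_weather(sim)
    sdoh = generate_sdoh(sim)
    W = generate_adjacency(sim.n_rows, sim.n_cols)
    events, truth = generate_events(sim, weather, sdoh, W)
    hio.write_weather(weather, p["weather"])
    hio.write_sdoh(sdoh, p["sdoh"])
    hio.write_adjacency(W, sim.county_ids, p["adjacency"])
    hio.write_events(events, p["events"])
    hio.write_truth(truth, p["truth"])
    return {
        "n_counties": sim.n_counties,
        "n_weather_rows": len(weather),
        "n_events_generated": len(events),
    }


def run_exposure(config: RunConfig) -> dict:
    """County exposure metrics (tmax/tmean/tmin/himax, deg C) from weather."""
    p = _paths(config)
    weather = hio.read_weather(p["weather"])
    hi_f = heat_index(c_to_f(weather["tmax_c"].to_numpy()), weather["rh_pct"].to_numpy())
    exposure = weather.assign(himax_c=f_to_c(hi_f))[
        ["county_id", "date", "tmax_c", "tmean_c", "tmin_c", "himax_c"]
    ]
    validate_exposure(exposure)
    hio.write_exposure(exposure, p["exposure"])
    return {"n_exposure_rows": len(exposure)}


def run_casecrossover(config: RunConfig) -> dict:
    """Classify, deduplicate, select metric/lag, and fit county ORs."""
    p = _paths(config)
    events = hio.read_events(p["events"])
    exposure = hio.read_exposure(p["exposure"])
    n_read = len(events)
    events["outcome"] = [classify_outcome(c) for c in events["icd9"]]
    unclassified = int(events["outcome"].isna().sum())
    events = events.dropna(subset=["outcome"])
    events = deduplicate_events(events, config.dedup_windows)
    n_deduped = len(events)

    lookup = ExposureLookup.from_series(exposure)
    seed = int(stage_seed(config.seed, "referents").generate_state(1)[0] % (2**31))

    counts: dict = {
        "events_read": n_read,
        "events_unclassified": unclassified,
        "events_after_dedup": n_deduped,
    }
    if config.metric == "auto":
        (metric, lag), grid = select_best_metric_lag(
            events, lookup, min_cases=config.min_cases, seed=seed, season=config.season,
            lags=tuple(range(config.max_lag + 1)), scheme=config.referent_scheme,
        )
        grid.to_csv(p["aic_grid"], index=False)
        counts["aic_grid_cells"] = len(grid)
    else:
        metric, lag = config.metric, int(config.lag)
    counts["metric"] = metric
    counts["lag"] = lag

    strata = build_strata(events, lookup, metric, lag, seed=seed, season=config.season,
                          scheme=config.referent_scheme)
    counts["strata_built"] = strata.n_strata
    counts["referents"] = strata.n_referents
    counts["strata_dropped_missing_exposure"] = strata.n_dropped_missing
    counts["cases_dropped_no_referent"] = strata.n_dropped_referent

    ors = estimate_county_ors(
        events, lookup, metric, lag, min_cases=config.min_cases,
        seed=seed, season=config.season, scheme=config.referent_scheme,
    )
    hio.write_county_ors(ors, p["county_or"])
    n_candidates = events.groupby(["outcome", "stream"])["county_id"].nunique().sum()
    counts["counties_fitted"] = len(ors)
    counts["counties_below_min_cases"] = int(n_candidates - len(ors))
    return counts


def run_spatial(config: RunConfig) -> dict:
    """Stage 2 on the county ORs: prune -> stepwise -> aspatial/spatial choice."""
    p = _paths(config)
    ors = hio.read_county_ors(p["county_or"])
    sdoh = hio.read_sdoh(p["sdoh"])
    county_order = list(sdoh["county_id"])
    W = hio.read_adjacency(p["adjacency"], county_order)
    counts: dict = {"stage2_cells": 0, "stage2_models": [], "stage2_skipped": []}
    if ors.empty:
        logger.warning("no county estimates; stage 2 skipped")
        counts["stage2_skipped"].append({"reason": "no county OR estimates"})
        hio.write_stage2([], p["stage2"])
        return counts
    results = stage2_analysis(
        ors, sdoh, W, county_order,
        threshold=config.corr_threshold,
        n_permutations=config.permutations,
        alpha=config.alpha,
        use_log_or=config.use_log_or,
        stepwise_spatial=config.stepwise_spatial,
        seed=config.seed,
    )
    hio.write_stage2(results, p["stage2"])
    counts["stage2_cells"] = len(results)
    for r in results:
        if r.skipped_reason:
            counts["stage2_skipped"].append(
                {"outcome": r.outcome, "stream": r.stream, "reason": r.skipped_reason}
            )
        else:
            counts["stage2_models"].append(
                {
                    "outcome": r.outcome,
                    "stream": r.stream,
                    "model_type": r.model_type,
                    "n_variables_selected": len(r.coefficients),
                    "aic": r.aic,
                    "moran_p": r.moran_p,
                }
            )
    return counts


def run_pipeline(config: RunConfig) -> dict:
    """All four stages in order; returns (and writes) the run report."""
    p = _paths(config)
    report = {"seed": config.seed, "workdir": str(p["root"])}
    for name, stage in (
        ("simulate", run_simulate),
        ("exposure", run_exposure),
        ("casecrossover", run_casecrossover),
        ("spatial", run_spatial),
    ):
        try:
            report[name] = stage(config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    p["report"].write_text(json.dumps(report, indent=1, sort_keys=True, default=str))
    return report
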