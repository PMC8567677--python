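"""Stage 1: county heat-morbidity odds ratios from a case-crossover design.

Each deduplicated health event is its own stratum: the exposure on the
case day is contrasted with the exposure on three same-weekday referent
days inside a 28-day comparison window (offsets of +/-7, +/-14 or +/-21
days; controls = 3 x analyzed cases exactly).  By default the referents
are the other members of the case's fixed 28-day calendar stratum, which
is exactly unbiased under the null; a case-anchored random-sign scheme is
available as an alternative.  Because each patient serves as their own
control, time-invariant confounders cancel by design, and the weekly
offsets cancel day-of-week cycles.

The conditional logistic likelihood is implemented directly: with one case
and three referents per stratum s and scalar exposure x,

    l(beta) = sum_s [ beta * x_case,s - log sum_j exp(beta * x_j,s) ]

is maximized by Newton-Raphson from beta = 0.  exp(beta) is the odds ratio
per deg C.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import (
    DEDUP_WINDOWS,
    METRICS,
    MIN_CASES_DEFAULT,
    REFERENT_OFFSETS,
    SeasonWindow,
)
from .exposure import ExposureLookup

logger = logging.getLogger(__name__)

__all__ = [
    "classify_outcome",
    "deduplicate_events",
    "select_referents",
    "build_strata",
    "StrataSet",
    "conditional_logistic_fit",
    "CLFit",
    "estimate_county_ors",
    "select_best_metric_lag",
]

_DIVERGENCE_BOUND = 10.0
_MAX_ITER = 50


# ---------------------------------------------------------------------------
# outcome classification and deduplication
# ---------------------------------------------------------------------------

#: Heat-related external-cause codes matched literally.
_HEAT_ECODES = frozenset({"E900.0", "E900.1", "E900.9"})


def classify_outcome(icd9: str) -> str | None:
    """Map an ICD-9 (or E-) code string to its heat-sensitive outcome class.

    Ranges: cardiovascular 390-459, dehydration 276.51, heat-related 992.x
    plus E900.0/.1/.9, acute renal 584.5-584.9, respiratory 460-519.
    Codes outside every range, and unparseable codes (with a logged
    warning), map to ``None``.
    """
    code = str(icd9).strip().upper()
    if not code:
        logger.warning("empty ICD-9 code")
        return None
    if code.startswith("E"):
        return "heat_related" if code in _HEAT_ECODES else None
    try:
        value = float(code)
    except ValueError:
        logger.warning("unparseable ICD-9 code %r", icd9)
        return None
    if abs(value - 276.51) < 1e-9:
        return "dehydration"
    if 390 <= value < 460:
        return "cardiovascular"
    if 460 <= value < 520:
        return "respiratory"
    if 584.5 <= value < 585:
        return "acute_renal"
    if 992 <= value < 993:
        return "heat_related"
    return None


def deduplicate_events(
    events: pd.DataFrame, windows: Mapping[str, int] = DEDUP_WINDOWS
) -> pd.DataFrame:
    """Drop re-visits by the same patient for the same outcome.

    Scanning each patient-outcome stream chronologically, a visit fewer
    than ``windows[outcome]`` days after the last *retained* visit is
    dropped; the first visit is always retained.  Requires an ``outcome``
    column (see :func:`classify_outcome`).
    """
    if "outcome" not in events.columns:
        raise ValueError("events need an 'outcome' column; classify ICD-9 codes first")
    unknown = set(events["outcome"].unique()) - set(windows)
    if unknown:
        raise ValueError(f"no dedup window for outcome(s): {sorted(unknown)}")
    if events.empty:
        return events.copy()

    df = events.sort_values(["patient_id", "outcome", "date"], kind="mergesort")
    ords = np.asarray([d.toordinal() for d in df["date"]], dtype=np.int64)
    pid = df["patient_id"].to_numpy()
    out = df["outcome"].to_numpy()
    win = np.asarray([windows[o] for o in out], dtype=np.int64)

    n = len(df)
    new_group = np.ones(n, dtype=bool)
    new_group[1:] = (pid[1:] != pid[:-1]) | (out[1:] != out[:-1])
    starts = np.flatnonzero(new_group)
    ends = np.r_[starts[1:], n]

    keep = np.ones(n, dtype=bool)
    multi = ends - starts > 1  # singleton patient-outcome streams need no scan
    for a, b in zip(starts[multi], ends[multi]):
        last_kept = ords[a]
        for i in range(a + 1, b):
            if ords[i] - last_kept < win[i]:
                keep[i] = False
            else:
                last_kept = ords[i]
    kept = df[keep]
    n_dropped = len(df) - len(kept)
    if n_dropped:
        logger.info("deduplication dropped %d of %d events", n_dropped, len(df))
    return kept.sort_index().reset_index(drop=True)


# ---------------------------------------------------------------------------
# referent selection
# ---------------------------------------------------------------------------

def _mix64(x: np.ndarray) -> np.ndarray:
    """SplitMix64 finalizer: a fast, well-scrambled integer hash."""
    x = np.asarray(x, dtype=np.uint64)
    with np.errstate(over="ignore"):
        x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        return x ^ (x >> np.uint64(31))


def _referent_signs(
    patient_ids: np.ndarray, date_ordinals: np.ndarray, seed: int
) -> np.ndarray:
    """Deterministic +/-1 sign per (event, offset), keyed on patient id and
    date (never on row index) so estimates are row-order invariant."""
    base = _mix64(
        np.uint64(seed % (2**31))
        ^ _mix64(np.asarray(patient_ids, dtype=np.uint64))
        ^ _mix64(np.asarray(date_ordinals, dtype=np.uint64) * np.uint64(0x9E3779B97F4A7C15))
    )
    signs = np.empty((len(patient_ids), len(REFERENT_OFFSETS)), dtype=np.int64)
    for j in range(len(REFERENT_OFFSETS)):
        bit = (base >> np.uint64(j)) & np.uint64(1)
        signs[:, j] = np.where(bit == 1, 1, -1)
    return signs


def _referent_ordinals(
    patient_ids: np.ndarray,
    date_ordinals: np.ndarray,
    start_ordinals: np.ndarray,
    end_ordinals: np.ndarray,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """(n, 3) referent date ordinals plus a per-event validity mask.

    For each offset magnitude the randomized side is taken; if it falls
    outside the season the other side is used; if both sides are out the
    event is flagged invalid (possible only for seasons < 43 days).
    """
    d = np.asarray(date_ordinals, dtype=np.int64)[:, None]
    lo = np.asarray(start_ordinals, dtype=np.int64)[:, None]
    hi = np.asarray(end_ordinals, dtype=np.int64)[:, None]
    offs = np.asarray(REFERENT_OFFSETS, dtype=np.int64)[None, :]
    signs = _referent_signs(patient_ids, date_ordinals, seed)
    first = d + signs * offs
    second = d - signs * offs
    first_ok = (first >= lo) & (first <= hi)
    second_ok = (second >= lo) & (second <= hi)
    referents = np.where(first_ok, first, second)
    valid = (first_ok | second_ok).all(axis=1)
    return referents, valid


_STRATUM_DAYS = 28  # comparison-window length: 4 same-weekday days per stratum


def _stratified_ordinals(
    date_ordinals: np.ndarray,
    start_ordinals: np.ndarray,
    end_ordinals: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-calendar time-stratified referents: (n, 3) ordinals + validity.

    The season is partitioned into consecutive 28-day blocks anchored at
    the season start; a case's stratum is the 4 same-weekday days of its
    block, and its referents are the other 3 (each at +/-7, +/-14 or
    +/-21 days).  Cases whose block is truncated by the season end (so
    the stratum has < 4 days) are flagged invalid and dropped upstream.
    """
    d = np.asarray(date_ordinals, dtype=np.int64)
    lo = np.asarray(start_ordinals, dtype=np.int64)
    hi = np.asarray(end_ordinals, dtype=np.int64)
    j = d - lo
    block_start = lo + (j // _STRATUM_DAYS) * _STRATUM_DAYS
    col = j % 7
    stratum = block_start[:, None] + col[:, None] + 7 * np.arange(4, dtype=np.int64)[None, :]
    valid = (stratum[:, -1] <= hi) & (j >= 0)
    own = stratum == d[:, None]
    referents = stratum[~own].reshape(-1, 3)
    return referents, valid


def select_referents(
    case_date: _dt.date,
    season_bounds: tuple[_dt.date, _dt.date],
    rng: np.random.Generator | None = None,
    scheme: str = "time_stratified",
) -> list[_dt.date]:
    """Three referent dates at |offset| in {7, 14, 21} days from the case.

    ``scheme="time_stratified"`` (default): the season is cut into fixed
    28-day blocks from the season start and the referents are the other
    three same-weekday days of the case's block -- exactly unbiased under
    the null because, within a stratum, every day is equally likely to be
    the case.  Raises for cases in a truncated trailing block.

    ``scheme="random_sign"``: one referent per offset magnitude 7/14/21,
    side chosen with equal probability, falling back to the other side at
    the season boundary.  Keeps every case but is subject to a small
    selection bias when exposure trends within the season.
    """
    lo, hi = season_bounds
    if not (lo <= case_date <= hi):
        raise ValueError(f"case date {case_date} outside season {lo}..{hi}")
    if scheme == "time_stratified":
        refs, valid = _stratified_ordinals(
            np.asarray([case_date.toordinal()]),
            np.asarray([lo.toordinal()]),
            np.asarray([hi.toordinal()]),
        )
        if not valid[0]:
            raise ValueError(
                f"case {case_date} falls in a season-truncated stratum; no complete referent set"
            )
        return [_dt.date.fromordinal(int(o)) for o in refs[0]]
    if scheme != "random_sign":
        raise ValueError(f"unknown referent scheme {scheme!r}")
    if rng is None:
        raise ValueError("random_sign scheme needs an rng")
    out = []
    for k in REFERENT_OFFSETS:
        sign = 1 if rng.random() < 0.5 else -1
        cand = case_date + _dt.timedelta(days=sign * k)
        if not (lo <= cand <= hi):
            cand = case_date + _dt.timedelta(days=-sign * k)
        if not (lo <= cand <= hi):
            raise ValueError(f"both +/-{k}-day referents out of season for case {case_date}")
        out.append(cand)
    return out


# ---------------------------------------------------------------------------
# strata
# ---------------------------------------------------------------------------

@dataclass
class StrataSet:
    """Matched 1:3 strata for one exposure metric at one lag.

    ``exposures`` is (n, 4) with the case exposure in column 0; rows align
    with ``county_ids`` / ``case_ordinals`` / ``referent_ordinals``.
    """

    metric: str
    lag: int
    exposures: np.ndarray
    county_ids: np.ndarray
    case_ordinals: np.ndarray
    referent_ordinals: np.ndarray
    n_dropped_missing: int = 0
    n_dropped_referent: int = 0

    @property
    def n_strata(self) -> int:
        return len(self.exposures)

    @property
    def n_referents(self) -> int:
        return self.n_strata * len(REFERENT_OFFSETS)


def _season_bounds_arrays(
    dates: Iterable[_dt.date], season: SeasonWindow
) -> tuple[np.ndarray, np.ndarray]:
    years = sorted({d.year for d in dates})
    lo = {y: season.bounds(y)[0].toordinal() for y in years}
    hi = {y: season.bounds(y)[1].toordinal() for y in years}
    lo_arr = np.asarray([lo[d.year] for d in dates], dtype=np.int64)
    hi_arr = np.asarray([hi[d.year] for d in dates], dtype=np.int64)
    return lo_arr, hi_arr


def build_strata(
    events: pd.DataFrame,
    lookup: ExposureLookup,
    metric: str,
    lag: int,
    seed: int = 0,
    season: SeasonWindow | None = None,
    scheme: str = "time_stratified",
) -> StrataSet:
    """One matched stratum per retained event for (metric, lag).

    The lag-k exposure on day d is the metric on d - k; strata with any
    missing exposure (e.g. lags reaching before the season start) are
    dropped and counted, as are cases without a complete referent set
    (see :func:`select_referents` for the two schemes).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if lag < 0:
        raise ValueError("lag must be non-negative")
    season = season or SeasonWindow()
    if events.empty:
        empty = np.empty((0, 4))
        return StrataSet(metric, lag, empty, np.empty(0, object), np.empty(0, np.int64),
                         np.empty((0, 3), np.int64))

    dates = list(events["date"])
    ords = np.asarray([d.toordinal() for d in dates], dtype=np.int64)
    pids = events["patient_id"].to_numpy()
    lo, hi = _season_bounds_arrays(dates, season)
    if scheme == "time_stratified":
        referents, valid = _stratified_ordinals(ords, lo, hi)
    elif scheme == "random_sign":
        referents, valid = _referent_ordinals(pids, ords, lo, hi, seed)
    else:
        raise ValueError(f"unknown referent scheme {scheme!r}")
    n_dropped_referent = int((~valid).sum())
    if n_dropped_referent:
        logger.info("dropped %d cases with no in-season referent", n_dropped_referent)

    rows = lookup.county_rows(events["county_id"])
    all_ords = np.column_stack([ords, referents])  # (n, 4), case first
    x = lookup.values(metric, np.repeat(rows, 4), (all_ords - lag).ravel()).reshape(-1, 4)
    has_missing = np.isnan(x).any(axis=1)
    complete = valid & ~has_missing
    n_dropped_missing = int((valid & has_missing).sum())
    if n_dropped_missing:
        logger.info("dropped %d strata with missing exposure at lag %d", n_dropped_missing, lag)

    return StrataSet(
        metric=metric,
        lag=lag,
        exposures=x[complete],
        county_ids=events["county_id"].to_numpy()[complete],
        case_ordinals=ords[complete],
        referent_ordinals=referents[complete],
        n_dropped_missing=n_dropped_missing,
        n_dropped_referent=n_dropped_referent,
    )


# ---------------------------------------------------------------------------
# conditional logistic likelihood
# ---------------------------------------------------------------------------

@dataclass
class CLFit:
    """Conditional logistic fit of a scalar exposure on 1:m matched strata."""

    beta: float
    se: float
    loglik: float
    aic: float
    n_strata: int
    converged: bool
    degenerate: bool = False

    @property
    def or_value(self) -> float:
        return float(np.exp(self.beta))


def _cl_loglik_parts(beta: float, x: np.ndarray):
    """(loglik, score, information) of the stratum likelihood at beta.

    x is (n, 4), case in column 0, centered per stratum for stability
    (the conditional likelihood is invariant to per-stratum shifts).
    """
    eta = beta * x
    m = eta.max(axis=1, keepdims=True)
    w = np.exp(eta - m)
    denom = w.sum(axis=1)
    p = w / denom[:, None]
    m1 = (p * x).sum(axis=1)
    m2 = (p * x * x).sum(axis=1)
    loglik = float((eta[:, 0] - (np.log(denom) + m[:, 0])).sum())
    score = float((x[:, 0] - m1).sum())
    info = float((m2 - m1 * m1).sum())
    return loglik, score, info


def conditional_logistic_fit(strata: np.ndarray | StrataSet) -> CLFit:
    """Newton-Raphson maximization of the matched-set likelihood.

    Starts from beta = 0 with a score tolerance of 1e-10 (scaled by the
    stratum count); |beta| escaping beyond 10 -- as happens when the case
    exposure is the stratum maximum everywhere -- is capped and flagged
    non-converged.  Strata with no exposure contrast carry no information;
    if every stratum is contrast-free the fit is flagged degenerate with
    beta = 0 and infinite SE.
    """
    x = strata.exposures if isinstance(strata, StrataSet) else np.asarray(strata, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("strata must be a 2D array with the case in column 0")
    n = len(x)
    if n == 0:
        raise ValueError("no strata to fit")
    x = x - x.mean(axis=1, keepdims=True)  # per-stratum centering (likelihood-invariant)

    if np.allclose(x, 0.0):
        ll = -n * np.log(x.shape[1])
        return CLFit(beta=0.0, se=np.inf, loglik=ll, aic=2.0 - 2.0 * ll,
                     n_strata=n, converged=True, degenerate=True)

    # the MLE does not exist when the case exposure is the stratum max
    # (or min) in every stratum: the likelihood increases monotonically in
    # beta; cap at the divergence bound and flag
    if np.all(x[:, 0] >= x[:, 1:].max(axis=1)) or np.all(x[:, 0] <= x[:, 1:].min(axis=1)):
        beta = float(np.sign((x[:, 0] - x[:, 1:].mean(axis=1)).sum()) * _DIVERGENCE_BOUND)
        ll, score, info = _cl_loglik_parts(beta, x)
        se = 1.0 / np.sqrt(info) if info > 0 else np.inf
        return CLFit(beta=beta, se=se, loglik=ll, aic=2.0 - 2.0 * ll,
                     n_strata=n, converged=False)

    tol = 1e-10 * max(1.0, float(n))
    beta = 0.0
    converged = False
    for _ in range(_MAX_ITER):
        ll, score, info = _cl_loglik_parts(beta, x)
        if info <= 0:
            break
        step = score / info
        beta += step
        if abs(beta) > _DIVERGENCE_BOUND:
            beta = np.sign(beta) * _DIVERGENCE_BOUND
            ll, score, info = _cl_loglik_parts(beta, x)
            se = 1.0 / np.sqrt(info) if info > 0 else np.inf
            return CLFit(beta=float(beta), se=se, loglik=ll, aic=2.0 - 2.0 * ll,
                         n_strata=n, converged=False)
        if abs(score) < tol:
            converged = True
            break
    ll, score, info = _cl_loglik_parts(beta, x)
    if not converged and abs(score) < 1e-6 * max(1.0, float(n)):
        converged = True  # score numerically flat; accept
    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    return CLFit(beta=float(beta), se=float(se), loglik=ll, aic=2.0 - 2.0 * ll,
                 n_strata=n, converged=converged)


# ---------------------------------------------------------------------------
# county estimates and metric/lag selection
# ---------------------------------------------------------------------------

def estimate_county_ors(
    events: pd.DataFrame,
    lookup: ExposureLookup,
    metric: str,
    lag: int,
    min_cases: int = MIN_CASES_DEFAULT,
    seed: int = 0,
    season: SeasonWindow | None = None,
    scheme: str = "time_stratified",
) -> pd.DataFrame:
    """Per-county odds ratios for one (metric, lag), by outcome and stream.

    Counties with fewer than ``min_cases`` retained strata are omitted (and
    logged) -- mirroring the mapping convention of leaving small-count
    counties blank.
    """
    if "outcome" not in events.columns:
        raise ValueError("events need an 'outcome' column")
    records = []
    for (outcome, stream), group in events.groupby(["outcome", "stream"], sort=True):
        strata = build_strata(group, lookup, metric, lag, seed=seed, season=season, scheme=scheme)
        order = np.argsort(strata.county_ids, kind="mergesort")
        cids = strata.county_ids[order]
        x = strata.exposures[order]
        bounds = np.flatnonzero(np.r_[True, cids[1:] != cids[:-1], True])
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b - a < min_cases:
                logger.info("county %s %s/%s: %d cases < %d, omitted",
                            cids[a], outcome, stream, b - a, min_cases)
                continue
            fit = conditional_logistic_fit(x[a:b])
            records.append(
                {
                    "county_id": cids[a],
                    "outcome": outcome,
                    "stream": stream,
                    "metric": metric,
                    "lag": lag,
                    "beta": fit.beta,
                    "se": fit.se,
                    "or": fit.or_value,
                    "n_cases": fit.n_strata,
                    "aic": fit.aic,
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=["county_id", "outcome", "stream", "metric", "lag", "beta", "se",
                 "or", "n_cases", "aic", "converged"],
    )


def select_best_metric_lag(
    events: pd.DataFrame,
    lookup: ExposureLookup,
    metrics: Sequence[str] = METRICS,
    lags: Sequence[int] = tuple(range(11)),
    min_cases: int = MIN_CASES_DEFAULT,
    seed: int = 0,
    season: SeasonWindow | None = None,
    scheme: str = "time_stratified",
) -> tuple[tuple[str, int], pd.DataFrame]:
    """Exposure metric and lag minimizing the AIC summed over counties.

    Returns the winning (metric, lag) plus the full metric x lag AIC grid
    (44 rows for 4 metrics x lags 0..10).
    """
    rows = []
    for metric in metrics:
        for lag in lags:
            ors = estimate_county_ors(events, lookup, metric, lag, min_cases=min_cases,
                                      seed=seed, season=season, scheme=scheme)
            rows.append(
                {
                    "metric": metric,
                    "lag": lag,
                    "total_aic": float(ors["aic"].sum()) if len(ors) else np.nan,
                    "n_counties": len(ors),
                    "n_strata": int(ors["n_cases"].sum()) if len(ors) else 0,
                }
            )
    grid = pd.DataFrame(rows)
    fitted = grid.dropna(subset=["total_aic"])
    if fitted.empty:
        raise ValueError("no metric/lag cell produced any county fit")
    best = fitted.sort_values(["total_aic", "metric", "lag"], kind="mergesort").iloc[0]
    return (str(best["metric"]), int(best["lag"])), grid
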