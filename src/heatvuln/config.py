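"""Configuration objects shared across the pipeline.

The study design is a warm-season (May through September) analysis of
heat-sensitive morbidity at the county level.  :class:`SeasonWindow` pins
the analysis calendar, :class:`SimConfig` collects every knob of the
synthetic-data generator, and :class:`RunConfig` collects the constants of
the two-stage analysis (referent offsets, dedup windows, case-count gate,
collinearity threshold, significance level).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

#: Health outcome classes analysed, keyed by their ICD-9 groupings.
OUTCOMES = ("cardiovascular", "dehydration", "heat_related", "acute_renal", "respiratory")

#: Care streams: emergency department visits and hospital admissions.
STREAMS = ("ED", "HSP")

#: Daily exposure metrics: max/mean/min temperature and max Heat Index.
METRICS = ("tmax", "tmean", "tmin", "himax")

#: Referent offsets (days) of the semi-symmetric bidirectional design:
#: one referent at +/-7, one at +/-14, one at +/-21 days from the case day,
#: i.e. a 28-day comparison window with 3 controls per case.
REFERENT_OFFSETS = (7, 14, 21)

#: Re-visit windows (days) within which subsequent visits by the same
#: patient for the same outcome are treated as the same illness episode.
DEDUP_WINDOWS: Mapping[str, int] = {
    "dehydration": 7,
    "heat_related": 7,
    "respiratory": 7,
    "cardiovascular": 28,
    "acute_renal": 28,
}

#: Counties with fewer retained cases than this are not fitted.
MIN_CASES_DEFAULT = 30

#: Pairwise |Pearson r| above which covariates are pruned before stage 2.
CORR_THRESHOLD_DEFAULT = 0.7

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class SeasonWindow:
    """Within-year analysis window, default May 1 through September 30."""

    start_month: int = 5
    start_day: int = 1
    end_month: int = 9
    end_day: int = 30

    def __post_init__(self) -> None:
        s = (self.start_month, self.start_day)
        e = (self.end_month, self.end_day)
        # validates the day-of-month too
        _dt.date(2001, *s)
        _dt.date(2001, *e)
        if e <= s:
            raise ValueError(f"season end {e} must fall after season start {s}")

    def bounds(self, year: int) -> tuple[_dt.date, _dt.date]:
        return (
            _dt.date(year, self.start_month, self.start_day),
            _dt.date(year, self.end_month, self.end_day),
        )

    def contains(self, d: _dt.date) -> bool:
        lo, hi = self.bounds(d.year)
        return lo <= d <= hi

    def dates(self, year: int) -> list[_dt.date]:
        lo, hi = self.bounds(year)
        return [lo + _dt.timedelta(days=i) for i in range((hi - lo).days + 1)]

    def n_days(self, year: int) -> int:
        lo, hi = self.bounds(year)
        return (hi - lo).days + 1


@dataclass(frozen=True)
class SDOHSpec:
    """Multivariate-normal design for the county covariate table.

    ``corr`` is the target correlation matrix; ``lower``/``upper`` clip the
    sampled values to their natural range (percent variables to [0, 100]).
    """

    names: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    corr: tuple[tuple[float, ...], ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]

    def __post_init__(self) -> None:
        k = len(self.names)
        if not (k == len(self.means) == len(self.sds) == len(self.lower) == len(self.upper)):
            raise ValueError("SDOHSpec field lengths disagree")
        c = np.asarray(self.corr, dtype=float)
        if c.shape != (k, k):
            raise ValueError(f"correlation matrix must be {k}x{k}, got {c.shape}")
        if not np.allclose(c, c.T):
            raise ValueError("correlation matrix must be symmetric")

    @property
    def corr_matrix(self) -> np.ndarray:
        return np.asarray(self.corr, dtype=float)


def default_sdoh_spec() -> SDOHSpec:
    """Ten-variable county covariate design at realistic Florida scales.

    Means and spreads mimic county summary statistics for a large warm-state
    study area.  Per-capita income and median household income are planted
    at r = 0.95 to exercise collinearity pruning; age/retirement-share and
    income/unemployment correlations are moderate.
    """
    names = (
        "median_age",
        "over_65_years",
        "female",
        "unemployment_rate",
        "farming_fishing_mining_forestry",
        "construction_extraction",
        "installation_maintenance_repair",
        "per_capita_income",
        "median_household_income",
        "one_parent_families",
    )
    means = (42.0, 18.3, 48.7, 12.6, 2.5, 7.8, 4.1, 23.1, 44.3, 34.3)
    sds = (5.9, 6.8, 3.7, 2.5, 4.5, 2.2, 1.1, 5.9, 7.5, 6.0)
    k = len(names)
    c = np.eye(k)

    def put(i: int, j: int, r: float) -> None:
        c[i, j] = c[j, i] = r

    put(0, 1, 0.60)   # median age ~ share over 65
    put(7, 8, 0.95)   # per-capita income ~ median household income (planted > 0.7)
    put(3, 7, -0.40)  # unemployment ~ per-capita income
    put(3, 8, -0.38)  # unemployment ~ household income
    lower = (20.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 0.0)
    upper = (90.0, 100.0, 100.0, 100.0, 100.0, 100.0, 100.0, np.inf, np.inf, 100.0)
    return SDOHSpec(
        names=names,
        means=means,
        sds=sds,
        corr=tuple(tuple(row) for row in c),
        lower=lower,
        upper=upper,
    )


@dataclass(frozen=True)
class SimConfig:
    """Synthetic-study conditions.

    A ``n_rows`` x ``n_cols`` lattice of counties (default 7 x 10 = 70,
    approximating a 67-county state on a queen-contiguity-friendly grid),
    five warm seasons, and a daily event process whose county log odds
    ratio per degree C is a known linear function of the covariates:

        beta_c = gamma0 + sum_k gamma[k] * sdoh_c[k] + spatial/iid noise

    Daily counts are Poisson with rate
    ``baseline_rate * exp(beta_c * (tmean - county mean tmean))`` so that
    the case-crossover odds ratio per degree C equals ``exp(beta_c)``.
    """

    n_rows: int = 7
    n_cols: int = 10
    years: tuple[int, ...] = (2008, 2009, 2010, 2011, 2012)
    season: SeasonWindow = field(default_factory=SeasonWindow)
    baseline_rate: float = 2.35
    gamma: Mapping[str, float] = field(
        default_factory=lambda: {"over_65_years": 0.0015, "per_capita_income": -0.002}
    )
    gamma0: float = 0.05
    beta_noise_sd: float = 0.005
    spatial_rho: float = 0.0
    duplicate_fraction: float = 0.05
    outcome: str = "dehydration"
    stream: str = "ED"
    sdoh: SDOHSpec = field(default_factory=default_sdoh_spec)
    # weather-process parameters (deg C unless noted)
    t_base: float = 26.5
    t_amplitude: float = 2.0
    county_offset_sd: float = 0.8
    ar_phi: float = 0.7
    ar_sd: float = 0.85
    daily_range_sd: float = 0.5
    rh_mean: float = 70.0
    rh_sd: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("lattice dimensions must be positive")
        if len(self.years) == 0:
            raise ValueError("years must be non-empty")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be non-negative")
        for name in ("beta_noise_sd", "county_offset_sd", "ar_sd", "daily_range_sd", "rh_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 <= self.spatial_rho < 1.0):
            raise ValueError("spatial_rho must lie in [0, 1)")
        if not (0.0 <= self.duplicate_fraction <= 1.0):
            raise ValueError("duplicate_fraction must lie in [0, 1]")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.stream not in STREAMS:
            raise ValueError(f"unknown stream {self.stream!r}")
        unknown = set(self.gamma) - set(self.sdoh.names)
        if unknown:
            raise ValueError(f"gamma refers to covariates not in the SDOH design: {sorted(unknown)}")

    @property
    def n_counties(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def county_ids(self) -> list[str]:
        width = max(3, len(str(self.n_counties)))
        return [f"C{i:0{width}d}" for i in range(1, self.n_counties + 1)]

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Derive a per-stage seed from the global seed.

    A fixed key-derivation scheme (global seed plus a stable stage index)
    so each stage can be rerun in isolation with identical randomness.
    """
    stages = ("weather", "sdoh", "events", "referents", "moran", "stage2")
    try:
        idx = stages.index(stage)
    except ValueError:
        raise ValueError(f"unknown stage {stage!r}; expected one of {stages}") from None
    return np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=(idx,))


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (paths plus analysis constants)."""

    workdir: str = "heatvuln_run"
    sim: SimConfig = field(default_factory=SimConfig)
    season: SeasonWindow = field(default_factory=SeasonWindow)
    metric: str = "auto"  # one of METRICS, or "auto" for AIC selection
    lag: int | None = 0   # ignored when metric == "auto"
    referent_scheme: str = "time_stratified"  # or "random_sign"
    max_lag: int = 10
    min_cases: int = MIN_CASES_DEFAULT
    corr_threshold: float = CORR_THRESHOLD_DEFAULT
    permutations: int = 999
    alpha: float = ALPHA_DEFAULT
    use_log_or: bool = False
    stepwise_spatial: bool = False
    dedup_windows: Mapping[str, int] = field(default_factory=lambda: dict(DEDUP_WINDOWS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.metric != "auto" and self.metric not in METRICS:
            raise ValueError(f"metric must be 'auto' or one of {METRICS}")
        if self.metric != "auto" and (self.lag is None or not (0 <= self.lag <= self.max_lag)):
            raise ValueError("lag must lie in [0, max_lag] when metric is fixed")
        if self.referent_scheme not in ("time_stratified", "random_sign"):
            raise ValueError("referent_scheme must be 'time_stratified' or 'random_sign'")
        if self.min_cases <= 0:
            raise ValueError("min_cases must be positive")
        if not (0 < self.corr_threshold):
            raise ValueError("corr_threshold must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.permutations < 1:
            raise ValueError("permutations must be positive")
        for k, v in self.dedup_windows.items():
            if k not in OUTCOMES:
                raise ValueError(f"dedup window for unknown outcome {k!r}")
            if v <= 0:
                raise ValueError("dedup windows must be positive")
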