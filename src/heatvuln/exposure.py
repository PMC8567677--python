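"""Daily county-level heat-exposure metrics.

Builds the four exposure metrics used in warm-season heat epidemiology --
daily maximum, mean, and minimum air temperature and daily maximum Heat
Index (HI) -- from cell/ZIP-level weather records, aggregates them to the
county level with census-population weights, and provides lagged exposure
lookup for the case-crossover stage.

The canonical internal unit is degrees Celsius (odds ratios downstream are
per deg C); the Heat Index is evaluated in Fahrenheit, where its
regression polynomial is defined, and converted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import METRICS

__all__ = [
    "heat_index",
    "c_to_f",
    "f_to_c",
    "daily_metrics",
    "population_weighted_series",
    "build_lag_matrix",
    "ExposureLookup",
    "validate_exposure",
]

# Rothfusz regression coefficients for HI(T deg F, RH %), in the order
# 1, T, R, TR, T^2, R^2, T^2 R, T R^2, T^2 R^2.
_HI_COEFFS = (
    -42.379,
    2.049015,
    10.143331,
    -0.224755,
    -6.83783e-3,
    -5.481717e-2,
    1.22874e-3,
    8.5282e-4,
    -1.99e-6,
)

_T_POLY_THRESHOLD_F = 80.0


def c_to_f(t_c):
    return np.asarray(t_c, dtype=float) * 9.0 / 5.0 + 32.0


def f_to_c(t_f):
    return (np.asarray(t_f, dtype=float) - 32.0) * 5.0 / 9.0


def _rothfusz(t, r):
    c0, c1, c2, c3, c4, c5, c6, c7, c8 = _HI_COEFFS
    return (
        c0
        + c1 * t
        + c2 * r
        + c3 * t * r
        + c4 * t * t
        + c5 * r * r
        + c6 * t * t * r
        + c7 * t * r * r
        + c8 * t * t * r * r
    )


def heat_index(temperature_f, relative_humidity, *, adjustments: bool = True):
    """Heat Index (deg F) from air temperature (deg F) and RH (%).

    For T >= 80 deg F: the nine-term Rothfusz regression polynomial with
    the standard NWS adjustments -- a low-humidity subtraction for
    RH < 13 % and 80-112 deg F, and a high-humidity addition for
    RH > 85 % and 80-87 deg F.  Below 80 deg F the simple-formula average
    ``0.5 * (T + 61 + (T - 68) * 1.2 + R * 0.094)`` is returned.  Gating
    on T keeps the index strictly monotone in T above 80 deg F; the cost
    is a seam at 80 deg F of up to ~2 deg F for moderate humidity (and up
    to ~2.8 deg F near RH 80 %), a known quirk of the two-branch
    convention.

    ``adjustments=False`` evaluates the bare polynomial everywhere (used to
    check the polynomial against an independent transcription).

    Raises ``ValueError`` for humidity outside [0, 100].
    """
    t = np.asarray(temperature_f, dtype=float)
    r = np.asarray(relative_humidity, dtype=float)
    t, r = np.broadcast_arrays(t, r)
    if np.any((r < 0) | (r > 100)):
        raise ValueError("relative humidity must lie in [0, 100] percent")

    poly = _rothfusz(t, r)
    if not adjustments:
        return poly if poly.ndim else float(poly)

    hi = poly.copy()
    low = (r < 13) & (t >= 80) & (t <= 112)
    if np.any(low):
        adj = ((13.0 - r) / 4.0) * np.sqrt(np.clip(17.0 - np.abs(t - 95.0), 0.0, None) / 17.0)
        hi = np.where(low, hi - adj, hi)
    high = (r > 85) & (t >= 80) & (t <= 87)
    if np.any(high):
        adj = ((r - 85.0) / 10.0) * ((87.0 - t) / 5.0)
        hi = np.where(high, hi + adj, hi)
    simple = 0.5 * (t + 61.0 + (t - 68.0) * 1.2 + r * 0.094)
    hi = np.where(t < _T_POLY_THRESHOLD_F, simple, hi)
    return hi if hi.ndim else float(hi)


def daily_metrics(observations: pd.DataFrame) -> pd.DataFrame:
    """Per-cell daily tmax/tmean/tmin/himax (deg C) from weather records.

    ``observations`` needs columns ``cell_id``, ``date``, ``temp_c``,
    ``rh_pct`` and may carry several rows (e.g. hours) per cell-day; himax
    is the maximum over the day's rows of the Heat Index at that row's
    humidity.  Missing temperatures raise, naming the gap.
    """
    required = {"cell_id", "date", "temp_c", "rh_pct"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"weather table missing columns: {sorted(missing)}")
    obs = observations.copy()
    bad = obs["temp_c"].isna() | obs["rh_pct"].isna()
    if bad.any():
        row = obs[bad].iloc[0]
        raise ValueError(f"missing weather value for cell {row['cell_id']} on {row['date']}")
    hi_c = f_to_c(heat_index(c_to_f(obs["temp_c"].to_numpy()), obs["rh_pct"].to_numpy()))
    obs["_hi_c"] = hi_c
    grouped = obs.groupby(["cell_id", "date"], sort=True)
    out = grouped.agg(
        tmax_c=("temp_c", "max"),
        tmean_c=("temp_c", "mean"),
        tmin_c=("temp_c", "min"),
        himax_c=("_hi_c", "max"),
    ).reset_index()
    return out


def population_weighted_series(
    cell_daily: pd.DataFrame, weights: pd.DataFrame
) -> pd.DataFrame:
    """Aggregate ZIP/cell daily metrics to counties with population weights.

    ``cell_daily`` has ``cell_id`` plus the metric columns from
    :func:`daily_metrics`; ``weights`` maps each ZIP to exactly one county
    with a non-negative population (``zip_id``, ``county_id``,
    ``population``).  County metric = population-weighted mean of its ZIPs'
    metrics, per day.
    """
    for col in ("zip_id", "county_id", "population"):
        if col not in weights.columns:
            raise ValueError(f"weights table missing column {col!r}")
    if (weights["population"] < 0).any():
        raise ValueError("populations must be non-negative")
    if weights["zip_id"].duplicated().any():
        dup = weights.loc[weights["zip_id"].duplicated(), "zip_id"].iloc[0]
        raise ValueError(f"ZIP {dup!r} mapped to more than one county")
    totals = weights.groupby("county_id")["population"].sum()
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"county with zero total population: {zero.index[0]!r}")

    metric_cols = [c for c in ("tmax_c", "tmean_c", "tmin_c", "himax_c") if c in cell_daily.columns]
    merged = cell_daily.merge(
        weights.rename(columns={"zip_id": "cell_id"}), on="cell_id", how="inner"
    )
    w = merged["population"].to_numpy(dtype=float)
    for col in metric_cols:
        merged[col] = merged[col].to_numpy(dtype=float) * w
    agg = merged.groupby(["county_id", "date"], sort=True)[metric_cols + ["population"]].sum()
    for col in metric_cols:
        agg[col] = agg[col] / agg["population"]
    return agg.drop(columns="population").reset_index()


def validate_exposure(series: pd.DataFrame) -> pd.DataFrame:
    """Check the county exposure invariants (tmin <= tmean <= tmax)."""
    required = {"county_id", "date", "tmax_c", "tmean_c", "tmin_c", "himax_c"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"exposure table missing columns: {sorted(missing)}")
    bad = (series["tmin_c"] > series["tmean_c"] + 1e-9) | (
        series["tmean_c"] > series["tmax_c"] + 1e-9
    )
    if bad.any():
        row = series[bad].iloc[0]
        raise ValueError(
            f"temperature ordering violated for county {row['county_id']} on {row['date']}"
        )
    return series


_METRIC_COLS = {m: f"{m}_c" for m in METRICS}


def build_lag_matrix(series: pd.DataFrame, max_lag: int = 10) -> pd.DataFrame:
    """Long county x date x lag exposure table.

    The lag-k value on date d is the metric on d - k; dates absent from the
    input (e.g. before the season start) yield missing values, and strata
    touching them are dropped downstream.
    """
    if max_lag < 0:
        raise ValueError("max_lag must be non-negative")
    validate_exposure(series)
    base = series[["county_id", "date"]].copy()
    metric_cols = list(_METRIC_COLS.values())
    frames = []
    for k in range(max_lag + 1):
        shifted = series[["county_id", "date"] + metric_cols].copy()
        shifted["date"] = pd.to_datetime(shifted["date"]) + pd.Timedelta(days=k)
        merged = base.assign(date=pd.to_datetime(base["date"])).merge(
            shifted, on=["county_id", "date"], how="left"
        )
        merged.insert(2, "lag", k)
        frames.append(merged)
    return pd.concat(frames, ignore_index=True).sort_values(
        ["county_id", "date", "lag"], ignore_index=True
    )


@dataclass
class ExposureLookup:
    """O(1) vectorized lookup of a county's metric on an arbitrary date.

    Internally a dense ``(n_counties, n_ordinal_days)`` array per metric
    with NaN outside the observed (in-season) dates.
    """

    county_index: dict
    base_ordinal: int
    arrays: dict  # metric -> 2D float array

    @classmethod
    def from_series(cls, series: pd.DataFrame) -> "ExposureLookup":
        validate_exposure(series)
        counties = sorted(series["county_id"].unique())
        county_index = {c: i for i, c in enumerate(counties)}
        dates = pd.to_datetime(series["date"])
        ordinals = dates.map(pd.Timestamp.toordinal).to_numpy(dtype=np.int64)
        base = int(ordinals.min())
        width = int(ordinals.max()) - base + 1
        rows = series["county_id"].map(county_index).to_numpy(dtype=np.int64)
        cols = ordinals - base
        arrays = {}
        for metric, col in _METRIC_COLS.items():
            a = np.full((len(counties), width), np.nan)
            a[rows, cols] = series[col].to_numpy(dtype=float)
            arrays[metric] = a
        return cls(county_index=county_index, base_ordinal=base, arrays=arrays)

    def values(self, metric: str, county_rows: np.ndarray, ordinals: np.ndarray) -> np.ndarray:
        """Metric values for (county row index, date ordinal) pairs; NaN if absent."""
        if metric not in self.arrays:
            raise KeyError(f"unknown metric {metric!r}; expected one of {tuple(self.arrays)}")
        a = self.arrays[metric]
        cols = np.asarray(ordinals, dtype=np.int64) - self.base_ordinal
        ok = (cols >= 0) & (cols < a.shape[1])
        out = np.full(cols.shape, np.nan)
        rows = np.asarray(county_rows, dtype=np.int64)
        out[ok] = a[rows[ok], cols[ok]]
        return out

    def county_rows(self, county_ids) -> np.ndarray:
        try:
            return np.asarray([self.county_index[c] for c in county_ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"county {exc.args[0]!r} absent from exposure series") from None
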