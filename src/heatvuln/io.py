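"""Reading and writing the pipeline's CSV/JSON artifacts.

Every artifact round-trips: ``read_x(write_x(obj)) == obj``.  Dates are
ISO-8601, county ids are opaque strings, temperatures are deg C.  Schema
violations raise with the offending column/row named.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import OUTCOMES, STREAMS

__all__ = [
    "read_events", "write_events",
    "read_exposure", "write_exposure",
    "read_weather", "write_weather",
    "read_sdoh", "write_sdoh",
    "read_adjacency", "write_adjacency",
    "read_county_ors", "write_county_ors",
    "write_stage2", "read_stage2",
    "write_truth", "read_truth",
]

_EVENT_COLS = ["patient_id", "date", "icd9", "stream", "county_id", "zip_id"]
_EXPOSURE_COLS = ["county_id", "date", "tmax_c", "tmean_c", "tmin_c", "himax_c"]
_WEATHER_COLS = ["county_id", "date", "tmax_c", "tmean_c", "tmin_c", "rh_pct"]
_OR_COLS = ["county_id", "outcome", "stream", "metric", "lag", "beta", "se", "or",
            "n_cases", "aic", "converged"]


def _require(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file missing columns: {missing}")


def _parse_dates(df: pd.DataFrame, what: str) -> pd.DataFrame:
    try:
        parsed = pd.to_datetime(df["date"], format="%Y-%m-%d")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{what}: unparseable ISO-8601 date ({exc})") from None
    df = df.copy()
    df["date"] = [d.date() for d in parsed]
    return df


def write_events(events: pd.DataFrame, path) -> Path:
    path = Path(path)
    out = events[_EVENT_COLS].copy()
    out["date"] = [d.isoformat() for d in out["date"]]
    out.to_csv(path, index=False)
    return path


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"icd9": str, "county_id": str, "zip_id": str})
    _require(df, _EVENT_COLS, "events")
    bad = ~df["stream"].isin(STREAMS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"events row {row}: unknown stream {df['stream'].iloc[row]!r} "
            f"(expected one of {STREAMS})"
        )
    return _parse_dates(df, "events")


def write_weather(weather: pd.DataFrame, path) -> Path:
    path = Path(path)
    out = weather[_WEATHER_COLS].copy()
    out["date"] = [d.isoformat() for d in out["date"]]
    out.to_csv(path, index=False)
    return path


def read_weather(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"county_id": str})
    _require(df, _WEATHER_COLS, "weather")
    return _parse_dates(df, "weather")


def write_exposure(series: pd.DataFrame, path) -> Path:
    path = Path(path)
    out = series[_EXPOSURE_COLS].copy()
    out["date"] = [d.isoformat() for d in out["date"]]
    out.to_csv(path, index=False)
    return path


def read_exposure(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"county_id": str})
    _require(df, _EXPOSURE_COLS, "exposure")
    return _parse_dates(df, "exposure")


def write_sdoh(sdoh: pd.DataFrame, path) -> Path:
    path = Path(path)
    sdoh.to_csv(path, index=False)
    return path


def read_sdoh(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"county_id": str})
    _require(df, ["county_id"], "sdoh")
    value_cols = [c for c in df.columns if c != "county_id"]
    bad = df[value_cols].isna()
    if bad.any().any():
        col = bad.any()[bad.any()].index[0]
        row = int(np.flatnonzero(bad[col].to_numpy())[0])
        raise ValueError(f"sdoh: missing value in column {col!r} at row {row}")
    return df


def write_adjacency(W: np.ndarray, county_ids, path) -> Path:
    """Edge list (i, j) of county-id pairs, both directions included."""
    path = Path(path)
    ii, jj = np.nonzero(np.asarray(W))
    ids = list(county_ids)
    pd.DataFrame({"i": [ids[a] for a in ii], "j": [ids[b] for b in jj]}).to_csv(
        path, index=False
    )
    return path


def read_adjacency(path, county_ids) -> np.ndarray:
    df = pd.read_csv(path, dtype=str)
    _require(df, ["i", "j"], "adjacency")
    ids = list(county_ids)
    index = {c: k for k, c in enumerate(ids)}
    unknown = (set(df["i"]) | set(df["j"])) - set(index)
    if unknown:
        raise ValueError(f"adjacency refers to unknown counties: {sorted(unknown)[:5]}")
    W = np.zeros((len(ids), len(ids)), dtype=np.int8)
    W[[index[a] for a in df["i"]], [index[b] for b in df["j"]]] = 1
    asym = np.argwhere(W != W.T)
    if len(asym):
        a, b = asym[0]
        raise ValueError(f"adjacency edge ({ids[a]}, {ids[b]}) is asymmetric; W must be symmetric")
    if np.any(np.diag(W)):
        raise ValueError("adjacency contains self-edges")
    return W


def write_county_ors(ors: pd.DataFrame, path) -> Path:
    path = Path(path)
    ors[_OR_COLS].to_csv(path, index=False)
    return path


def read_county_ors(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"county_id": str})
    _require(df, _OR_COLS, "county_or")
    bad = ~df["outcome"].isin(OUTCOMES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"county_or row {row}: unknown outcome {df['outcome'].iloc[row]!r}")
    return df


def write_stage2(results, path) -> Path:
    """Long-format stage-2 table: one row per (cell, variable) plus a
    model-level row (variable = '<model>') carrying the diagnostics."""
    rows = []
    for r in results:
        base = {
            "outcome": r.outcome, "stream": r.stream, "model_type": r.model_type,
            "rho": r.rho if r.rho is not None else "",
            "aic": r.aic, "moran_I": r.moran_I, "moran_p": r.moran_p,
            "ks_p": r.ks_p, "n_counties": r.n_counties,
        }
        rows.append({**base, "variable": "<model>", "estimate": "", "p": "",
                     "note": r.skipped_reason or ""})
        for var in r.coefficients.index:
            rows.append({**base, "variable": var, "estimate": r.coefficients[var],
                         "p": r.pvalues.get(var, ""), "note": ""})
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_stage2(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["outcome", "stream", "model_type", "variable"], "stage2")
    return df


def write_truth(truth, path) -> Path:
    path = Path(path)
    payload = {
        "gamma0": truth.gamma0,
        "gamma": dict(truth.gamma),
        "county_beta": {k: float(v) for k, v in truth.county_beta.items()},
        "county_beta_linear": {k: float(v) for k, v in truth.county_beta_linear.items()},
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())
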