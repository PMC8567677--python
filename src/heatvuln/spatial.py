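"""Stage 2: relating county odds ratios to social determinants of health.

The county odds ratios from the case-crossover stage become the dependent
variable of a county-level regression on demographic/socioeconomic
covariates.  The workflow is:

1. prune covariates until no pair has |Pearson r| above 0.7;
2. backward stepwise AIC variable selection from the full model;
3. fit an aspatial multiple linear regression, test residual normality
   (Kolmogorov-Smirnov) and residual spatial autocorrelation (global
   Moran's I with a Monte-Carlo permutation p-value);
4. fit a maximum-likelihood spatial lag model  y = rho W y + X beta + eps
   on binary queen-contiguity weights (not row-standardized), and report
   global average total impacts;
5. choose the spatial lag model iff residual autocorrelation is detected
   (permutation p <= alpha) or the spatial model has the lower AIC.

Moran's I, the spatial lag likelihood (log-determinant via the eigenvalues
of W), and the stepwise search are implemented here; ordinary least
squares is delegated to statsmodels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .config import ALPHA_DEFAULT, CORR_THRESHOLD_DEFAULT

logger = logging.getLogger(__name__)

__all__ = [
    "correlation_prune",
    "ols_fit",
    "OLSFit",
    "ks_normality",
    "morans_I",
    "MoranResult",
    "spatial_lag_fit",
    "SpatialLagFit",
    "total_impacts",
    "backward_stepwise_aic",
    "choose_model",
    "Stage2Result",
    "stage2_analysis",
    "validate_weights",
]


def validate_weights(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T):
        raise ValueError("W must be symmetric")
    if np.any(np.diag(W) != 0):
        raise ValueError("W must have a zero diagonal")
    return W


# ---------------------------------------------------------------------------
# collinearity pruning
# ---------------------------------------------------------------------------

def correlation_prune(
    table: pd.DataFrame,
    threshold: float = CORR_THRESHOLD_DEFAULT,
    drop_override: Sequence[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Drop covariates until no pair has |Pearson r| > ``threshold``.

    Greedy: while any offending pair remains, remove the member of the
    worst pair with the larger mean absolute correlation against the other
    remaining variables (ties broken by column order).  An explicit
    ``drop_override`` list bypasses the greedy search so a conventional
    drop set can be reproduced exactly.

    Returns (kept, dropped) column-name lists.
    """
    cols = [c for c in table.columns if c != "county_id"]
    if len(cols) < 2:
        raise ValueError("need at least 2 covariate columns")
    if len(table) < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    values = table[cols]
    constant = values.std(ddof=0) == 0
    if constant.any():
        raise ValueError(f"constant column (undefined correlation): {constant.idxmax()!r}")

    if drop_override is not None:
        unknown = set(drop_override) - set(cols)
        if unknown:
            raise ValueError(f"drop_override names unknown columns: {sorted(unknown)}")
        dropped = [c for c in cols if c in set(drop_override)]
        kept = [c for c in cols if c not in set(drop_override)]
        return kept, dropped

    corr = values.corr().abs()
    kept = list(cols)
    dropped: list[str] = []
    while True:
        sub = corr.loc[kept, kept].to_numpy(copy=True)
        np.fill_diagonal(sub, 0.0)
        worst = sub.max()
        if worst <= threshold:
            break
        i, j = np.unravel_index(int(np.argmax(sub)), sub.shape)
        # mean |r| of each member against the other remaining variables
        mean_i = sub[i].sum() / (len(kept) - 1)
        mean_j = sub[j].sum() / (len(kept) - 1)
        victim = kept[i] if mean_i >= mean_j else kept[j]
        if mean_i == mean_j:
            victim = kept[max(i, j)]  # tie: drop the later column
        dropped.append(victim)
        kept.remove(victim)
        if len(kept) < 2:
            break
    return kept, dropped


# ---------------------------------------------------------------------------
# aspatial model
# ---------------------------------------------------------------------------

@dataclass
class OLSFit:
    """Least-squares fit with the Gaussian-likelihood AIC convention
    ``AIC = 2 (p + 2) - 2 loglik`` (intercept and variance both counted)."""

    params: pd.Series
    se: pd.Series
    pvalues: pd.Series
    residuals: np.ndarray
    loglik: float
    aic: float
    n: int
    variables: list[str]
    rho: float | None = None

    @property
    def model_type(self) -> str:
        return "MLR"


def ols_fit(y: np.ndarray | pd.Series, X: pd.DataFrame | None) -> OLSFit:
    """Multiple linear regression with intercept; empty X -> intercept only."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is None or X.shape[1] == 0:
        X = pd.DataFrame(index=range(n))
    if len(X) != n:
        raise ValueError("y and X row counts differ")
    p = X.shape[1]
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        aliased = _aliased_columns(design, ["const"] + list(X.columns))
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")
    res = sm.OLS(y, design).fit()
    names = ["const"] + list(X.columns)
    return OLSFit(
        params=pd.Series(res.params, index=names),
        se=pd.Series(res.bse, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        residuals=np.asarray(res.resid),
        loglik=float(res.llf),
        aic=2.0 * (p + 2) - 2.0 * float(res.llf),
        n=n,
        variables=list(X.columns),
    )


def _aliased_columns(design: np.ndarray, names: list[str]) -> list[str]:
    """Columns linearly dependent on their predecessors (QR diagnostic)."""
    aliased = []
    for j in range(1, design.shape[1]):
        if np.linalg.matrix_rank(design[:, : j + 1]) == np.linalg.matrix_rank(design[:, :j]):
            aliased.append(names[j])
    return aliased


def ks_normality(residuals: np.ndarray) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test of standardized residuals
    against the standard normal; returns (statistic, asymptotic p)."""
    r = np.asarray(residuals, dtype=float)
    if len(r) < 5:
        raise ValueError("need at least 5 residuals")
    sd = r.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance residuals")
    z = (r - r.mean()) / sd
    stat, p = scipy.stats.kstest(z, "norm")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

@dataclass
class MoranResult:
    I: float
    expected_I: float
    p_value: float
    n_permutations: int


def morans_I(
    values: np.ndarray,
    W: np.ndarray,
    n_permutations: int = 999,
    rng: np.random.Generator | int | None = None,
) -> MoranResult:
    """Global Moran's I with a Monte-Carlo permutation p-value.

        I = (n / S0) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2),   z = x - mean(x)

    The permutation p is two-sided: the smaller of the >= and <= tail
    proportions (each computed as (1 + #extreme) / (1 + n_permutations))
    is doubled and capped at 1.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    W = validate_weights(W)
    if W.shape[0] != n:
        raise ValueError("W size does not match values")
    s0 = W.sum()
    if s0 == 0:
        raise ValueError("W has no nonzero entries")
    if np.ptp(x) == 0:
        raise ValueError("values are constant; Moran's I undefined")

    def stat(z: np.ndarray) -> float:
        zc = z - z.mean()
        return float(n / s0 * (zc @ W @ zc) / (zc @ zc))

    observed = stat(x)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    perms = rng.permuted(np.tile(x, (n_permutations, 1)), axis=1)
    zc = perms - perms.mean(axis=1, keepdims=True)
    perm_I = n / s0 * np.einsum("ij,jk,ik->i", zc, W, zc) / (zc * zc).sum(axis=1)
    p_hi = (1 + int((perm_I >= observed).sum())) / (1 + n_permutations)
    p_lo = (1 + int((perm_I <= observed).sum())) / (1 + n_permutations)
    p = min(1.0, 2.0 * min(p_hi, p_lo))
    return MoranResult(I=observed, expected_I=-1.0 / (n - 1), p_value=p,
                       n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# spatial lag model
# ---------------------------------------------------------------------------

@dataclass
class SpatialLagFit:
    """Maximum-likelihood fit of y = rho W y + X beta + eps.

    ``params``/``se``/``pvalues`` cover the intercept and predictors;
    ``impacts`` are global average total impacts n^-1 1' (I - rho W)^-1 1
    * beta_k for each predictor.  AIC counts p + 3 parameters (betas incl.
    intercept, rho, sigma^2).
    """

    rho: float
    rho_se: float
    params: pd.Series
    se: pd.Series
    pvalues: pd.Series
    impacts: pd.Series
    residuals: np.ndarray
    loglik: float
    aic: float
    n: int
    variables: list[str]
    converged: bool
    rho_interval: tuple[float, float]

    @property
    def model_type(self) -> str:
        return "spatial_lag"


def _concentrated_loglik(rho, eigvals, y, Wy, Q):
    """Concentrated log-likelihood at rho, up to a constant.

    l(rho) = sum log(1 - rho lambda_i) - (n/2) log(SSE(rho)/n), where
    SSE(rho) is from regressing (y - rho W y) on X (Q = orthonormal X basis).
    """
    n = len(y)
    u = y - rho * Wy
    resid = u - Q @ (Q.T @ u)
    sse = float(resid @ resid)
    with np.errstate(invalid="ignore"):
        logdet = np.log(1.0 - rho * eigvals).sum()
    return float(logdet - 0.5 * n * np.log(sse / n))


def spatial_lag_fit(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame | None,
    W: np.ndarray,
) -> SpatialLagFit:
    """ML spatial lag fit on symmetric binary weights.

    The log-determinant uses the precomputed eigenvalues of W,
    ``log|I - rho W| = sum log(1 - rho lambda_i)``, and rho is maximized
    over the feasible interval (1/lambda_min, 1/lambda_max) by bounded
    scalar search; beta comes from least squares on the filtered response
    at rho-hat, and standard errors from the asymptotic information
    matrix.  A rho-hat pinned at an interval endpoint is flagged
    non-converged; an all-zero W degenerates to OLS with rho forced to 0.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    W = validate_weights(W)
    if W.shape[0] != n:
        raise ValueError("W size does not match y")
    if X is None:
        X = pd.DataFrame(index=range(n))
    p = X.shape[1]
    if n <= p + 2:
        raise ValueError(f"need n > p + 2 (n={n}, p={p})")
    names = ["const"] + list(X.columns)
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")

    if not W.any():
        # rho unidentified without neighbours: fall back to OLS, flagged
        ols = ols_fit(y, X)
        sigma2 = float(ols.residuals @ ols.residuals) / n
        logger.warning("all-zero weight matrix: spatial lag degenerates to OLS")
        return SpatialLagFit(
            rho=0.0, rho_se=np.nan, params=ols.params, se=ols.se, pvalues=ols.pvalues,
            impacts=ols.params.drop("const"), residuals=ols.residuals,
            loglik=ols.loglik, aic=2.0 * (p + 3) - 2.0 * ols.loglik, n=n,
            variables=list(X.columns), converged=False, rho_interval=(-np.inf, np.inf),
        )

    eigvals = np.linalg.eigvalsh(W)
    lo = 1.0 / eigvals.min() if eigvals.min() < 0 else -np.inf
    hi = 1.0 / eigvals.max() if eigvals.max() > 0 else np.inf
    margin = 1e-6 * (hi - lo) if np.isfinite(hi - lo) else 1e-6
    Q, _ = np.linalg.qr(design)
    Wy = W @ y

    opt = scipy.optimize.minimize_scalar(
        lambda r: -_concentrated_loglik(r, eigvals, y, Wy, Q),
        bounds=(lo + margin, hi - margin),
        method="bounded",
        options={"xatol": 1e-10},
    )
    rho = float(opt.x)
    pinned = (rho - lo) < 1e-4 * (hi - lo) or (hi - rho) < 1e-4 * (hi - lo)
    if pinned:
        logger.warning("rho-hat pinned at feasible-interval endpoint: %.6f in (%.4f, %.4f)",
                       rho, lo, hi)

    A_y = y - rho * Wy
    beta, *_ = np.linalg.lstsq(design, A_y, rcond=None)
    resid = A_y - design @ beta
    sse = float(resid @ resid)
    sigma2 = sse / n
    logdet = float(np.log(1.0 - rho * eigvals).sum())
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet
    aic = 2.0 * (p + 3) - 2.0 * loglik

    # Asymptotic information matrix for (beta, rho, sigma^2) (Ord/Anselin):
    #   C = W (I - rho W)^-1
    A_inv = np.linalg.inv(np.eye(n) - rho * W)
    C = W @ A_inv
    CXb = C @ (design @ beta)
    k = design.shape[1]
    info = np.zeros((k + 2, k + 2))
    info[:k, :k] = design.T @ design / sigma2
    info[:k, k] = info[k, :k] = design.T @ CXb / sigma2
    info[k, k] = np.trace(C @ C + C.T @ C) + float(CXb @ CXb) / sigma2
    info[k, k + 1] = info[k + 1, k] = np.trace(C) / sigma2
    info[k + 1, k + 1] = n / (2.0 * sigma2**2)
    try:
        cov = np.linalg.inv(info)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        se_all = np.full(k + 2, np.nan)
    se = se_all[:k]
    rho_se = float(se_all[k])
    with np.errstate(divide="ignore", invalid="ignore"):
        zstats = beta / se
    pvals = 2.0 * scipy.stats.norm.sf(np.abs(zstats))

    params = pd.Series(beta, index=names)
    impacts = total_impacts(params.drop("const"), rho, W)
    return SpatialLagFit(
        rho=rho,
        rho_se=rho_se,
        params=params,
        se=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        impacts=impacts,
        residuals=resid,
        loglik=float(loglik),
        aic=float(aic),
        n=n,
        variables=list(X.columns),
        converged=not pinned,
        rho_interval=(lo, hi),
    )


def total_impacts(beta: pd.Series | Mapping[str, float], rho: float, W: np.ndarray) -> pd.Series:
    """Global average total impact per predictor.

    ATI_k = n^-1 1' (I - rho W)^-1 1 * beta_k -- the mean cumulative
    (direct + spillover) change in y from a one-unit change of predictor k
    in every county.
    """
    W = validate_weights(W)
    n = W.shape[0]
    A = np.eye(n) - rho * W
    try:
        v = np.linalg.solve(A, np.ones(n))
    except np.linalg.LinAlgError:
        raise ValueError("(I - rho W) is singular; impacts undefined") from None
    multiplier = float(v.sum()) / n
    beta = pd.Series(dict(beta)) if not isinstance(beta, pd.Series) else beta
    return beta * multiplier


# ---------------------------------------------------------------------------
# stepwise selection and model choice
# ---------------------------------------------------------------------------

def backward_stepwise_aic(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    fitter: Callable = ols_fit,
) -> tuple[list[str], object]:
    """Backward stepwise AIC variable selection.

    Starts from the full model and repeatedly deletes the single variable
    whose removal lowers AIC the most; stops when no deletion lowers AIC.
    Deterministic given column order.  Returns (selected, final fit).
    """
    current = list(X.columns)
    best_fit = fitter(y, X[current])  # raises before stepping if rank deficient
    while current:
        candidates = []
        for var in current:
            reduced = [c for c in current if c != var]
            fit = fitter(y, X[reduced])
            candidates.append((fit.aic, var, fit))
        candidates.sort(key=lambda t: (t[0], current.index(t[1])))
        best_aic, best_var, fit = candidates[0]
        if best_aic < best_fit.aic:
            current.remove(best_var)
            best_fit = fit
        else:
            break
    return current, best_fit


@dataclass
class Stage2Result:
    """Chosen stage-2 model for one outcome/stream cell."""

    outcome: str
    stream: str
    model_type: str                  # "MLR" or "spatial_lag"
    selected_variables: list[str]
    coefficients: pd.Series          # spatial lag: average total impacts
    pvalues: pd.Series
    rho: float | None
    aic: float
    moran_I: float
    moran_p: float
    ks_p: float
    n_counties: int
    ols_aic: float = np.nan
    spatial_aic: float = np.nan
    skipped_reason: str | None = None


def choose_model(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    W: np.ndarray,
    n_permutations: int = 999,
    alpha: float = ALPHA_DEFAULT,
    rng: np.random.Generator | int | None = None,
    outcome: str = "",
    stream: str = "",
) -> Stage2Result:
    """Aspatial-vs-spatial decision for one outcome/stream cell.

    Fits the aspatial model, tests its residuals (KS normality, Moran's I
    on the weights), fits the spatial lag model, and selects the spatial
    lag iff residual autocorrelation is detected (permutation p <= alpha)
    or the spatial AIC is strictly lower.
    """
    y = np.asarray(y, dtype=float)
    ols = ols_fit(y, X)
    ks_stat, ks_p = ks_normality(ols.residuals)
    moran = morans_I(ols.residuals, W, n_permutations=n_permutations, rng=rng)
    lag = spatial_lag_fit(y, X, W)
    use_spatial = (moran.p_value <= alpha) or (lag.aic < ols.aic)

    if use_spatial:
        coefs = lag.impacts
        pvals = lag.pvalues.drop("const")
        chosen_aic, model_type, rho = lag.aic, "spatial_lag", lag.rho
    else:
        coefs = ols.params.drop("const")
        pvals = ols.pvalues.drop("const")
        chosen_aic, model_type, rho = ols.aic, "MLR", None
    return Stage2Result(
        outcome=outcome,
        stream=stream,
        model_type=model_type,
        selected_variables=list(X.columns),
        coefficients=coefs,
        pvalues=pvals,
        rho=rho,
        aic=chosen_aic,
        moran_I=moran.I,
        moran_p=moran.p_value,
        ks_p=ks_p,
        n_counties=len(y),
        ols_aic=ols.aic,
        spatial_aic=lag.aic,
    )


def stage2_analysis(
    county_ors: pd.DataFrame,
    sdoh: pd.DataFrame,
    W: np.ndarray,
    county_order: Sequence[str],
    threshold: float = CORR_THRESHOLD_DEFAULT,
    drop_override: Sequence[str] | None = None,
    n_permutations: int = 999,
    alpha: float = ALPHA_DEFAULT,
    use_log_or: bool = False,
    stepwise_spatial: bool = False,
    seed: int = 0,
) -> list[Stage2Result]:
    """Prune -> stepwise -> model choice for every outcome/stream cell.

    ``county_ors`` is the stage-1 output at the selected metric/lag;
    ``W`` is the full-study weight matrix ordered as ``county_order`` and
    is subset to the counties with estimates in each cell.  Cells with
    fewer than max(10, p + 5) counties are skipped with a reason
    (small-count outcomes cannot support a model).
    """
    order_index = {c: i for i, c in enumerate(county_order)}
    unmatched = set(county_ors["county_id"]) - set(order_index)
    if unmatched:
        raise ValueError(f"counties missing from weights/order: {sorted(unmatched)[:5]}")
    unmatched = set(county_ors["county_id"]) - set(sdoh["county_id"])
    if unmatched:
        raise ValueError(f"counties missing from SDOH table: {sorted(unmatched)[:5]}")
    W = validate_weights(W)
    sdoh_indexed = sdoh.set_index("county_id")

    results: list[Stage2Result] = []
    for cell_idx, ((outcome, stream), group) in enumerate(
        county_ors.groupby(["outcome", "stream"], sort=True)
    ):
        group = group.sort_values("county_id", key=lambda s: s.map(order_index))
        counties = list(group["county_id"])
        kept, dropped = correlation_prune(
            sdoh_indexed.loc[counties].reset_index(),
            threshold=threshold,
            drop_override=drop_override,
        )
        p = len(kept)
        min_n = max(10, p + 5)
        if len(counties) < min_n:
            logger.info("%s/%s: only %d counties (< %d), skipped", outcome, stream,
                        len(counties), min_n)
            results.append(
                Stage2Result(
                    outcome=outcome, stream=stream, model_type="skipped",
                    selected_variables=[], coefficients=pd.Series(dtype=float),
                    pvalues=pd.Series(dtype=float), rho=None, aic=np.nan,
                    moran_I=np.nan, moran_p=np.nan, ks_p=np.nan,
                    n_counties=len(counties),
                    skipped_reason=f"{len(counties)} counties < required {min_n}",
                )
            )
            continue

        y = group["beta"].to_numpy() if use_log_or else group["or"].to_numpy()
        X = sdoh_indexed.loc[counties, kept].reset_index(drop=True)
        idx = np.asarray([order_index[c] for c in counties])
        W_sub = W[np.ix_(idx, idx)]

        if stepwise_spatial:
            fitter = lambda yy, XX: spatial_lag_fit(yy, XX, W_sub)  # noqa: E731
        else:
            fitter = ols_fit
        selected, _ = backward_stepwise_aic(y, X, fitter=fitter)
        rng = np.random.default_rng(np.random.SeedSequence((seed % (2**31), cell_idx)))
        result = choose_model(
            y, X[selected], W_sub, n_permutations=n_permutations, alpha=alpha,
            rng=rng, outcome=outcome, stream=stream,
        )
        results.append(result)
    return results
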