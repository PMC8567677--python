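import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from heatvuln.spatial import (
    backward_stepwise_aic,
    choose_model,
    correlation_prune,
    ks_normality,
    morans_I,
    ols_fit,
    spatial_lag_fit,
    stage2_analysis,
    total_impacts,
)
from heatvuln.synthetic import generate_adjacency


def brute_force_moran(x, W):
    """O(n^2) double-sum transcription of the Moran's I definition."""
    n = len(x)
    z = x - x.mean()
    num = sum(W[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return (n / W.sum()) * num / (z @ z)


class TestCorrelationPrune:
    @staticmethod
    def _table(rng, n=80):
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        return pd.DataFrame({"a": a, "b": b, "c": rng.normal(size=n)})

    def test_nothing_dropped_below_threshold(self, rng):
        kept, dropped = correlation_prune(self._table(rng))
        assert dropped == []
        assert kept == ["a", "b", "c"]

    def test_duplicated_column_drops_exactly_one(self, rng):
        t = self._table(rng)
        t["a_copy"] = t["a"]
        kept, dropped = correlation_prune(t)
        assert len(dropped) == 1
        assert dropped[0] in ("a", "a_copy")

    def test_planted_block_fully_resolved(self, rng):
        # three variables sharing one factor at r ~ 0.9; verify the
        # survivor set by full recomputation of all pairwise correlations
        n = 300
        f = rng.normal(size=n)
        t = pd.DataFrame(
            {
                "x1": f + 0.33 * rng.normal(size=n),
                "x2": f + 0.33 * rng.normal(size=n),
                "x3": f + 0.33 * rng.normal(size=n),
                "y1": rng.normal(size=n),
                "y2": rng.normal(size=n),
                "y3": rng.normal(size=n),
            }
        )
        kept, dropped = correlation_prune(t, threshold=0.7)
        corr = t[kept].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.7
        assert set(kept) >= {"y1", "y2", "y3"}

    def test_constant_column_rejected(self, rng):
        t = self._table(rng)
        t["flat"] = 3.0
        with pytest.raises(ValueError, match="flat"):
            correlation_prune(t)

    def test_override_list_is_used_verbatim(self, rng):
        t = self._table(rng)
        kept, dropped = correlation_prune(t, drop_override=["b"])
        assert kept == ["a", "c"] and dropped == ["b"]


class TestOLS:
    def test_exact_fit_zero_residuals(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        y = 2.0 + 3.0 * X["x"]
        fit = ols_fit(y, X)
        assert np.abs(fit.residuals).max() < 1e-10
        assert fit.params["x"] == pytest.approx(3.0)

    def test_empty_design_gives_mean(self, rng):
        y = rng.normal(5, 1, size=20)
        fit = ols_fit(y, None)
        assert fit.params["const"] == pytest.approx(y.mean())
        assert fit.variables == []

    def test_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(7)
        n, p = 50, 3
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=list("abc"))
        y = rng.normal(size=n)
        fit = ols_fit(y, X)
        design = np.column_stack([np.ones(n), X.to_numpy()])
        oracle = np.linalg.pinv(design.T @ design) @ design.T @ y
        assert np.allclose(fit.params.to_numpy(), oracle, atol=1e-8)
        # AIC counts intercept + p slopes + variance
        assert fit.aic == pytest.approx(2 * (p + 2) - 2 * fit.loglik)

    def test_rank_deficiency_names_aliased_column(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=30)})
        X["b"] = 2 * X["a"]
        with pytest.raises(ValueError, match="b"):
            ols_fit(rng.normal(size=30), X)


class TestKSNormality:
    def test_calibrated_under_null(self):
        r = np.random.default_rng(12).normal(size=1000)
        _, p = ks_normality(r)
        assert p > 0.01

    def test_power_under_heavy_tails(self):
        r = np.random.default_rng(12).standard_cauchy(size=1000)
        _, p = ks_normality(r)
        assert p < 0.01

    def test_statistic_matches_hand_computation(self):
        # D = max over sorted points of max(|i/n - F(x_i)|, |F(x_i) - (i-1)/n|)
        r = np.array([-2.0, -0.5, 0.1, 0.6, 2.2])
        z = (r - r.mean()) / r.std(ddof=1)
        F = scipy.stats.norm.cdf(np.sort(z))
        n = len(z)
        i = np.arange(1, n + 1)
        expected = max(np.abs(i / n - F).max(), np.abs(F - (i - 1) / n).max())
        stat, _ = ks_normality(r)
        assert stat == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ks_normality(np.ones(10))


class TestMoransI:
    def test_equals_bruteforce_double_sum(self, rng):
        for trial in range(5):
            n = int(rng.integers(6, 30))
            W = (rng.random((n, n)) < 0.3).astype(float)
            W = np.triu(W, 1)
            W = W + W.T
            if W.sum() == 0:
                W[0, 1] = W[1, 0] = 1.0
            x = rng.normal(size=n)
            res = morans_I(x, W, n_permutations=9, rng=rng)
            assert res.I == pytest.approx(brute_force_moran(x, W), abs=1e-12)

    def test_complete_graph_hand_value(self):
        W = 1.0 - np.eye(4)
        x = np.array([1.0, 1.0, -1.0, -1.0])
        res = morans_I(x, W, n_permutations=9, rng=1)
        assert res.I == pytest.approx(brute_force_moran(x, W), abs=1e-14)
        # hand enumeration: z = x, S0 = 12, cross-products sum = -4
        assert res.I == pytest.approx(4 / 12 * (-4) / 4, abs=1e-14)

    def test_expected_value_closed_form(self, rng):
        W = generate_adjacency(3, 3).astype(float)
        res = morans_I(rng.normal(size=9), W, n_permutations=9, rng=rng)
        assert res.expected_I == pytest.approx(-1 / 8)

    def test_null_calibration(self):
        # permutation p under a null (shuffled values) rejects ~5% of the time
        W = generate_adjacency(5, 5).astype(float)
        rejections = 0
        n_reps = 60
        for rep in range(n_reps):
            rng = np.random.default_rng(1000 + rep)
            x = rng.normal(size=25)
            res = morans_I(x, W, n_permutations=199, rng=rng)
            rejections += res.p_value <= 0.05
        assert rejections / n_reps < 0.15

    def test_detects_planted_autocorrelation(self):
        # smooth surface over the lattice: strongly positive I, small p
        W = generate_adjacency(6, 6).astype(float)
        coords = np.array([(r, c) for r in range(6) for c in range(6)], dtype=float)
        x = coords[:, 0] + coords[:, 1]
        res = morans_I(x, W, n_permutations=499, rng=3)
        assert res.I > 0.5
        assert res.p_value <= 0.01

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError):
            morans_I(np.ones(9), generate_adjacency(3, 3).astype(float), rng=0)


class TestSpatialLag:
    @staticmethod
    def _lattice_data(rho, n_rows=7, n_cols=7, seed=5, beta=(1.0, 0.5, -0.8)):
        rng = np.random.default_rng(seed)
        W = generate_adjacency(n_rows, n_cols).astype(float)
        n = n_rows * n_cols
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["u", "v"])
        eta = beta[0] + X["u"] * beta[1] + X["v"] * beta[2] + rng.normal(0, 0.5, n)
        y = np.linalg.solve(np.eye(n) - rho * W, eta.to_numpy())
        return y, X, W

    def test_null_process_recovers_ols(self):
        y, X, W = self._lattice_data(rho=0.0)
        lag = spatial_lag_fit(y, X, W)
        ols = ols_fit(y, X)
        assert abs(lag.rho) < 3 * lag.rho_se
        assert np.allclose(lag.params.to_numpy(), ols.params.to_numpy(), atol=0.15)

    def test_recovers_planted_rho(self):
        # rho = 0.1 is safely inside the feasible interval of a
        # non-row-standardized 7x7 queen lattice (1/lambda_max ~ 0.17)
        y, X, W = self._lattice_data(rho=0.1, seed=5)
        lag = spatial_lag_fit(y, X, W)
        assert lag.converged
        assert abs(lag.rho - 0.1) < 3 * lag.rho_se

    def test_concentrated_likelihood_dominates_grid(self):
        from heatvuln.spatial import _concentrated_loglik

        y, X, W = self._lattice_data(rho=0.08, seed=9)
        lag = spatial_lag_fit(y, X, W)
        eigvals = np.linalg.eigvalsh(W)
        lo, hi = 1 / eigvals.min(), 1 / eigvals.max()
        design = np.column_stack([np.ones(len(y)), X.to_numpy()])
        Q, _ = np.linalg.qr(design)
        Wy = W @ y
        grid = np.linspace(lo + 1e-6, hi - 1e-6, 1000)
        ll_hat = _concentrated_loglik(lag.rho, eigvals, y, Wy, Q)
        ll_grid = max(_concentrated_loglik(r, eigvals, y, Wy, Q) for r in grid)
        assert ll_hat >= ll_grid - 1e-8

    def test_zero_weight_matrix_degenerates_to_ols(self, rng):
        n = 20
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = 1.0 + 2.0 * X["x"].to_numpy() + rng.normal(0, 0.1, n)
        lag = spatial_lag_fit(y, X, np.zeros((n, n)))
        ols = ols_fit(y, X)
        assert lag.rho == 0.0
        assert not lag.converged
        assert np.allclose(lag.params.to_numpy(), ols.params.to_numpy(), atol=1e-12)

    def test_asymmetric_weights_rejected(self, rng):
        W = np.zeros((10, 10))
        W[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            spatial_lag_fit(rng.normal(size=10), None, W)


class TestTotalImpacts:
    def test_identity_at_rho_zero(self):
        W = generate_adjacency(3, 3).astype(float)
        beta = pd.Series({"a": 1.3, "b": -0.4})
        impacts = total_impacts(beta, 0.0, W)
        pd.testing.assert_series_equal(impacts, beta)

    def test_zero_beta_zero_impact(self):
        W = generate_adjacency(3, 3).astype(float)
        assert total_impacts(pd.Series({"a": 0.0}), 0.05, W)["a"] == 0.0

    def test_matches_dense_inverse_oracle(self):
        W = generate_adjacency(3, 3).astype(float)
        rho = 0.05
        A_inv = np.linalg.inv(np.eye(9) - rho * W)
        expected = A_inv.sum() / 9 * 1.0
        got = total_impacts(pd.Series({"a": 1.0}), rho, W)["a"]
        assert got == pytest.approx(expected, abs=1e-10)


class TestStepwise:
    def test_pure_noise_predictor_removed(self):
        rng = np.random.default_rng(42)
        n = 200
        X = pd.DataFrame(
            {"real1": rng.normal(size=n), "real2": rng.normal(size=n),
             "noise": rng.normal(size=n)}
        )
        y = 1.0 + 2.0 * X["real1"] - 1.5 * X["real2"] + rng.normal(0, 1, n)
        selected, fit = backward_stepwise_aic(y, X)
        assert "noise" not in selected
        assert {"real1", "real2"} <= set(selected)
        # oracle: removing noise must beat keeping it on AIC
        assert fit.aic < ols_fit(y, X).aic

    def test_immediate_stop_returns_full_model(self):
        rng = np.random.default_rng(3)
        n = 150
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = 3 * X["a"] + 3 * X["b"] + rng.normal(0, 0.3, n)
        selected, _ = backward_stepwise_aic(y, X)
        assert selected == ["a", "b"]

    def test_local_optimality_against_exhaustive_subsets(self):
        rng = np.random.default_rng(17)
        n, p = 60, 4
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=list("abcd"))
        y = 1.5 * X["a"] + rng.normal(0, 1, n)
        selected, fit = backward_stepwise_aic(y, X)
        # exhaustive oracle over all 16 subsets
        best_aic = min(
            ols_fit(y, X[list(sub)]).aic
            for k in range(p + 1)
            for sub in itertools.combinations(X.columns, k)
        )
        assert fit.aic >= best_aic - 1e-9
        # no single deletion from the final set lowers AIC
        for var in selected:
            reduced = [c for c in selected if c != var]
            assert ols_fit(y, X[reduced]).aic >= fit.aic


class TestChooseModel:
    def test_independent_noise_prefers_mlr(self):
        W = generate_adjacency(5, 5).astype(float)
        picks = []
        for rep in range(20):
            rng = np.random.default_rng(300 + rep)
            X = pd.DataFrame({"x": rng.normal(size=25)})
            y = 1 + 0.5 * X["x"].to_numpy() + rng.normal(0, 0.3, 25)
            res = choose_model(y, X, W, n_permutations=199, rng=rng)
            picks.append(res.model_type)
        assert picks.count("MLR") >= 13

    def test_strong_lag_process_prefers_spatial(self):
        rng = np.random.default_rng(9)
        W = generate_adjacency(6, 6).astype(float)
        n = 36
        rho = 0.14  # near the top of the feasible interval (~0.17)
        X = pd.DataFrame({"x": rng.normal(size=n)})
        eta = 1 + 0.5 * X["x"].to_numpy() + rng.normal(0, 0.3, n)
        y = np.linalg.solve(np.eye(n) - rho * W, eta)
        res = choose_model(y, X, W, n_permutations=399, rng=rng)
        assert res.model_type == "spatial_lag"
        assert res.rho is not None

    def test_spatial_requires_strict_improvement(self, rng, monkeypatch):
        # identical AICs and a clean Moran p must yield MLR (tie rule)
        import heatvuln.spatial as sp

        W = generate_adjacency(4, 4).astype(float)
        X = pd.DataFrame({"x": rng.normal(size=16)})
        y = 1 + X["x"].to_numpy() + rng.normal(0, 0.3, 16)
        real_fit = sp.spatial_lag_fit

        def tied_fit(yy, XX, WW):
            out = real_fit(yy, XX, WW)
            out.aic = sp.ols_fit(yy, XX).aic  # force the tie
            return out

        monkeypatch.setattr(sp, "spatial_lag_fit", tied_fit)
        res = sp.choose_model(y, X, W, n_permutations=99, rng=np.random.default_rng(0))
        if res.moran_p > 0.05:
            assert res.model_type == "MLR"


class TestStage2Analysis:
    @staticmethod
    def _inputs(rng, n_rows=6, n_cols=6, n_small=0):
        n = n_rows * n_cols
        ids = [f"C{i:03d}" for i in range(1, n + 1)]
        W = generate_adjacency(n_rows, n_cols).astype(float)
        sdoh = pd.DataFrame(
            {
                "county_id": ids,
                "v1": rng.normal(10, 2, n),
                "v2": rng.normal(50, 5, n),
                "v3": rng.normal(0, 1, n),
            }
        )
        beta = 0.02 + 0.01 * (sdoh["v1"] - 10) / 2
        ors = pd.DataFrame(
            {
                "county_id": ids,
                "outcome": "dehydration",
                "stream": "ED",
                "metric": "tmean",
                "lag": 0,
                "beta": beta,
                "se": 0.005,
                "or": np.exp(beta) + rng.normal(0, 0.003, n),
                "n_cases": 100,
                "aic": 100.0,
                "converged": True,
            }
        )
        return ids, W, sdoh, ors

    def test_planted_variable_recovered(self, rng):
        ids, W, sdoh, ors = self._inputs(rng)
        results = stage2_analysis(ors, sdoh, W, ids, n_permutations=99, seed=1)
        (res,) = results
        assert res.model_type in ("MLR", "spatial_lag")
        assert "v1" in res.coefficients.index
        assert res.coefficients["v1"] > 0

    def test_small_cell_skipped_with_reason(self, rng):
        ids, W, sdoh, ors = self._inputs(rng)
        tiny = ors.head(5)
        (res,) = stage2_analysis(tiny, sdoh, W, ids, n_permutations=99, seed=1)
        assert res.model_type == "skipped"
        assert "5 counties" in res.skipped_reason

    def test_county_mismatch_rejected(self, rng):
        ids, W, sdoh, ors = self._inputs(rng)
        bad = ors.copy()
        bad.loc[0, "county_id"] = "C999"
        with pytest.raises(ValueError, match="C999"):
            stage2_analysis(bad, sdoh, W, ids, n_permutations=99, seed=1)

    def test_row_order_invariance(self, rng):
        ids, W, sdoh, ors = self._inputs(rng)
        a = stage2_analysis(ors, sdoh, W, ids, n_permutations=99, seed=2)
        shuffled = ors.sample(frac=1, random_state=5).reset_index(drop=True)
        b = stage2_analysis(shuffled, sdoh, W, ids, n_permutations=99, seed=2)
        pd.testing.assert_series_equal(a[0].coefficients, b[0].coefficients)
        assert a[0].moran_I == pytest.approx(b[0].moran_I, abs=1e-12)
        assert a[0].moran_p == b[0].moran_p
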