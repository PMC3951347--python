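"""Tests of the spatial GLS fit, diagnostics, model reduction and effect
translation."""

import warnings

import numpy as np
import pandas as pd
import pytest

from killzones import (
    diagnostics,
    drop_and_refit,
    effect_per_unit,
    fit_gls,
    reml_loglik,
)
from killzones.errors import CollinearityError
from killzones.habitat import HabitatMatrix
from killzones.regression import _FAMILIES


def simulate_gls(n, beta, tau2, sigma2, phi, rng, extent=1000.0):
    """Draw one dataset from the spatial linear model."""
    coords = rng.uniform(0, extent, size=(n, 2))
    X = rng.standard_normal((n, len(beta) - 1))
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    Sigma = tau2 * np.eye(n) + sigma2 * np.exp(-d / phi)
    y = beta[0] + X @ beta[1:] + np.linalg.cholesky(Sigma) @ rng.standard_normal(n)
    return y, X, coords


def dense_reml_oracle(y, Xmat, dists, tau2, sigma2, phi):
    """Independent dense-algebra evaluation: explicit inverse and
    determinant, no Cholesky solves."""
    n, p = Xmat.shape
    Sigma = tau2 * np.eye(n) + sigma2 * np.exp(-dists / phi)
    Si = np.linalg.inv(Sigma)
    _, logdet = np.linalg.slogdet(Sigma)
    XtSiX = Xmat.T @ Si @ Xmat
    _, logdet_x = np.linalg.slogdet(XtSiX)
    beta = np.linalg.inv(XtSiX) @ Xmat.T @ Si @ y
    r = y - Xmat @ beta
    return -0.5 * (logdet + logdet_x + r @ Si @ r + (n - p) * np.log(2 * np.pi))


class TestREMLLikelihood:
    def test_matches_dense_oracle(self, rng):
        n = 20
        y, X, coords = simulate_gls(n, np.array([1.0, 2.0, -1.0]), 0.5, 1.0, 200.0, rng)
        Xmat = np.column_stack([np.ones(n), X])
        d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        for params in [(0.5, 1.0, 200.0), (1.0, 0.3, 500.0), (2.0, 2.0, 50.0)]:
            mine = reml_loglik(y, Xmat, d, *params)
            oracle = dense_reml_oracle(y, Xmat, d, *params)
            assert mine == pytest.approx(oracle, abs=1e-8)


class TestFitGLS:
    def test_reduces_to_ols_under_independence(self, rng):
        n = 80
        y, X, coords = simulate_gls(n, np.array([5.0, 2.0, -1.0, 0.5]), 4.0, 0.0, 100.0, rng)
        fit = fit_gls(y, pd.DataFrame(X, columns=["a", "b", "c"]), coords, seed=0)
        Xmat = np.column_stack([np.ones(n), X])
        beta_ols = np.linalg.lstsq(Xmat, y, rcond=None)[0]
        assert np.allclose(fit.params.to_numpy(), beta_ols, atol=1e-6)
        assert fit.cov_params["sigma2"] <= 1e-8 * max(fit.cov_params["tau2"], 1.0)

    def test_residuals_plus_fitted_equal_response(self, rng):
        y, X, coords = simulate_gls(60, np.array([0.0, 1.0, 0.0]), 1.0, 1.0, 150.0, rng)
        fit = fit_gls(y, X, coords, seed=1)
        assert np.allclose(fit.residuals + fit.fitted, y, atol=1e-12)
        assert np.all(fit.se > 0)
        cp = fit.cov_params
        assert cp["tau2"] >= 0 and cp["sigma2"] >= 0 and cp["phi"] > 0

    def test_optimum_at_least_as_good_as_truth(self, rng):
        """The optimizer never converges to a point worse than the
        generating covariance parameters."""
        for rep in range(5):
            y, X, coords = simulate_gls(
                50, np.array([0.0, 1.5, -0.5]), 0.5, 1.0, 250.0,
                np.random.default_rng(rep),
            )
            fit = fit_gls(y, X, coords, seed=rep)
            Xmat = np.column_stack([np.ones(len(y)), X])
            d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
            ll_truth = reml_loglik(y, Xmat, d, 0.5, 1.0, 250.0)
            assert fit.loglik >= ll_truth - 1e-6

    def test_collinear_design_rejected(self, rng):
        n = 40
        X = rng.standard_normal((n, 2))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])  # exact linear combination
        y = rng.standard_normal(n)
        with pytest.raises(CollinearityError):
            fit_gls(y, X, rng.uniform(0, 100, size=(n, 2)), seed=0)

    def test_misaligned_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_gls(np.ones(10), rng.standard_normal((12, 2)),
                    rng.uniform(size=(10, 2)), seed=0)


class TestDiagnostics:
    def test_normality_null_calibration(self):
        """Decorrelated standard-normal residuals: the Shapiro test
        rejects at the 1% level in about 1% of replicates."""
        from killzones.regression import RegressionResult

        rng = np.random.default_rng(31)
        n = 150
        coords = rng.uniform(0, 1000, size=(n, 2))
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            e = rng.standard_normal(n)
            fitted = rng.uniform(0, 100, n)
            res = RegressionResult(
                params=pd.Series({"const": 0.0}), se=pd.Series({"const": 1.0}),
                cov_params={"tau2": 1.0, "sigma2": 0.0, "phi": 100.0},
                loglik=0.0, residuals=e, fitted=fitted,
            )
            rep = diagnostics(res, coords)
            rejections += rep.normality_p < 0.01
        # 3 binomial SEs around the nominal 1%
        se = np.sqrt(0.01 * 0.99 / n_rep)
        assert abs(rejections / n_rep - 0.01) <= 3 * se

    def test_heteroscedasticity_power(self):
        """Variance growing ~5x across the fitted range is flagged at the
        5% level in >= 80% of replicates."""
        from killzones.regression import RegressionResult

        rng = np.random.default_rng(77)
        n = 150
        coords = rng.uniform(0, 1000, size=(n, 2))
        flagged = 0
        for _ in range(100):
            fitted = np.sort(rng.uniform(0, 100, n))
            sd = 1.0 + 4.0 * fitted / 100.0  # 5x spread
            e = rng.standard_normal(n) * sd
            res = RegressionResult(
                params=pd.Series({"const": 0.0}), se=pd.Series({"const": 1.0}),
                cov_params={"tau2": 1.0, "sigma2": 0.0, "phi": 100.0},
                loglik=0.0, residuals=e, fitted=fitted,
            )
            flagged += diagnostics(res, coords).het_p < 0.05
        assert flagged >= 80

    def test_constant_residuals_rejected(self):
        from killzones.regression import RegressionResult

        res = RegressionResult(
            params=pd.Series({"const": 0.0}), se=pd.Series({"const": 1.0}),
            cov_params={"tau2": 1.0, "sigma2": 0.0, "phi": 100.0},
            loglik=0.0, residuals=np.zeros(20), fitted=np.linspace(0, 1, 20),
        )
        with pytest.raises(ValueError):
            diagnostics(res, np.random.default_rng(0).uniform(size=(20, 2)))


class TestDropAndRefit:
    def test_no_op_when_all_significant(self, rng):
        y, X, coords = simulate_gls(
            100, np.array([0.0, 5.0, -5.0]), 1.0, 0.0, 100.0, rng
        )
        Xdf = pd.DataFrame(X, columns=["strong_pos", "strong_neg"])
        fit = fit_gls(y, Xdf, coords, seed=0)
        assert all(abs(fit.params[t]) > fit.se[t] for t in ("strong_pos", "strong_neg"))
        reduced = drop_and_refit(fit, y, Xdf, coords)
        assert reduced is fit

    def test_planted_null_removed_and_strong_effects_stable(self):
        removed_null = 0
        shifts = []
        for rep in range(60):
            rng = np.random.default_rng(3000 + rep)
            y, X, coords = simulate_gls(
                120, np.array([0.0, 2.0, -1.5, 0.0]), 1.0, 0.0, 100.0, rng
            )
            Xdf = pd.DataFrame(X, columns=["s1", "s2", "null"])
            fit = fit_gls(y, Xdf, coords, seed=rep)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                red = drop_and_refit(fit, y, Xdf, coords)
            if "null" in red.removed:
                removed_null += 1
            for term in ("s1", "s2"):
                if term in red.params.index:
                    shifts.append(
                        abs(red.params[term] - fit.params[term]) / abs(fit.params[term])
                    )
        assert removed_null > 30  # removed in the majority of runs
        assert np.mean(shifts) < 0.10

    def test_reduced_model_carries_provenance(self, rng):
        y, X, coords = simulate_gls(
            100, np.array([0.0, 3.0, 0.0]), 1.0, 0.0, 100.0, rng
        )
        Xdf = pd.DataFrame(X, columns=["keepme", "dropme"])
        fit = fit_gls(y, Xdf, coords, seed=0)
        red = drop_and_refit(fit, y, Xdf, coords)
        if red is not fit:
            assert red.removed == ["dropme"]
            assert "reduced_from" in red.meta


class TestEffectPerUnit:
    def _fixture(self, rng=None):
        rng = rng or np.random.default_rng(1005)  # iid-error realization
        n = 120
        raw = pd.DataFrame(
            {
                "elevation": rng.uniform(100, 400, n),
                "conifer": rng.uniform(0, 1, n),
            }
        )
        means, sds = raw.mean(), raw.std(ddof=1)
        std = (raw - means) / sds
        matrix = HabitatMatrix(
            data=std, standardized=True, column_means=means, column_sds=sds
        )
        beta = np.array([10.0, 3.0, -2.0])
        y = beta[0] + std.to_numpy() @ beta[1:] + 0.5 * rng.standard_normal(n)
        coords = rng.uniform(0, 1000, size=(n, 2))
        return y, matrix, coords

    def test_zero_delta_gives_zero(self, rng):
        y, matrix, coords = self._fixture(rng)
        fit = fit_gls(y, matrix, coords, seed=0)
        assert effect_per_unit(fit, "elevation", 0.0, matrix) == 0.0

    def test_definitional_arithmetic(self):
        from killzones.regression import RegressionResult

        matrix = HabitatMatrix(
            data=pd.DataFrame({"elevation": [0.0, 1.0]}),
            standardized=True,
            column_means=pd.Series({"elevation": 200.0}),
            column_sds=pd.Series({"elevation": 10.0}),
        )
        res = RegressionResult(
            params=pd.Series({"const": 0.0, "elevation": 1.0}),
            se=pd.Series({"const": 1.0, "elevation": 1.0}),
            cov_params={}, loglik=0.0, residuals=np.zeros(2), fitted=np.zeros(2),
        )
        assert effect_per_unit(res, "elevation", 10.0, matrix) == pytest.approx(1.0)

    def test_matches_unstandardized_ols_slope(self):
        """Independence case: when the fit selects independent errors,
        beta_std / sd equals the ordinary-regression slope on the
        covariate in natural units."""
        import statsmodels.api as sm

        y, matrix, coords = self._fixture()
        fit = fit_gls(y, matrix, coords, seed=0)
        assert fit.cov_params["sigma2"] == 0.0  # independent-error solution
        raw = matrix.data * matrix.column_sds + matrix.column_means
        ols = sm.OLS(y, sm.add_constant(raw)).fit()
        for name in ("elevation", "conifer"):
            assert effect_per_unit(fit, name, 1.0, matrix) == pytest.approx(
                ols.params[name], abs=1e-8
            )

    def test_absent_covariate_rejected(self, rng):
        y, matrix, coords = self._fixture(rng)
        fit = fit_gls(y, matrix, coords, seed=0)
        with pytest.raises(ValueError):
            effect_per_unit(fit, "slope", 1.0, matrix)
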