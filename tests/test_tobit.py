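"""Censored-regression likelihood, fitting, partial effects and inference."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.stats import norm

import chokelab as cl
from chokelab.errors import DesignError, DomainError, NonIdentifiableError
from chokelab.tobit import (TobitDesign, _loglik_terms, _marginal_loglik,
                            expected_choking, fit_tobit, tobit_loglik,
                            wald_inference)


def simulate_tobit(beta, sigma, tau, n_groups, rng, lam_sd=1.5):
    """Simulate (participant x condition) choking scores from the model."""
    pids = [f"S{i:03d}" for i in range(n_groups)]
    lam_c = rng.normal(0.0, lam_sd, n_groups)
    lam_c -= lam_c.mean()
    u = rng.normal(0.0, tau, n_groups)
    rows = []
    for i, pid in enumerate(pids):
        for cond in (0.0, 1.0):
            x = np.array([1.0, cond, lam_c[i]])[: len(beta)]
            ystar = x @ np.asarray(beta) + u[i] + rng.normal(0.0, sigma)
            rows.append((pid, cond, max(ystar, 0.0), lam_c[i]))
    df = pd.DataFrame(rows, columns=["pid", "cond", "y", "lam_c"])
    X = np.column_stack([np.ones(len(df)), df["cond"], df["lam_c"]])[:, : len(beta)]
    groups = df["pid"].astype("category").cat.codes.to_numpy()
    names = ["const", "condition", "lambda_c"][: len(beta)]
    return TobitDesign(X=X, y=df["y"].to_numpy(), groups=groups, names=names)


class TestLoglik:
    def test_censored_at_zero_index(self):
        ll = tobit_loglik(np.array([0.0]), 1.0, np.ones((1, 1)), np.array([0.0]))
        assert ll == pytest.approx(np.log(0.5), abs=1e-9)

    def test_uncensored_at_mode(self):
        ll = tobit_loglik(np.array([3.0]), 1.0, np.ones((1, 1)), np.array([3.0]))
        assert ll == pytest.approx(norm.logpdf(0.0), abs=1e-9)

    def test_matches_numeric_integration_oracle(self, rng):
        # censored mass P(y* <= 0) by quadrature of the latent density,
        # uncensored contribution by the normal pdf itself
        for _ in range(50):
            sigma = rng.uniform(0.5, 10)
            # keep the censoring boundary within 4 SD so the quadrature
            # oracle itself is accurate to the asserted tolerance
            xb = rng.uniform(-4, 4) * sigma
            y = 0.0 if rng.random() < 0.5 else abs(rng.normal(xb, sigma))
            ll = _loglik_terms(np.array([xb]), sigma, np.ones((1, 1)),
                               np.array([y]))[0]
            if y <= 0:
                mass, _ = integrate.quad(
                    lambda v: norm.pdf(v, loc=xb, scale=sigma), -np.inf, 0,
                    epsabs=0.0, epsrel=1e-11)
                assert ll == pytest.approx(np.log(mass), abs=1e-8)
            else:
                assert ll == pytest.approx(norm.logpdf(y, loc=xb, scale=sigma),
                                           abs=1e-10)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(DomainError):
            tobit_loglik(np.zeros(1), 0.0, np.ones((1, 1)), np.zeros(1))

    def test_marginal_matches_quadrature_oracle(self, rng):
        # tiny two-participant problem: compare Gauss-Hermite marginal
        # likelihood against adaptive numeric integration over u
        design = simulate_tobit([5.0, -2.0], 4.0, 3.0, 2, rng)
        beta = np.array([5.0, -2.0])
        sigma, tau = 4.0, 3.0
        nodes, weights = np.polynomial.hermite.hermgauss(64)
        logw = np.log(weights) - 0.5 * np.log(np.pi)
        gh = _marginal_loglik(beta, sigma, tau, design.X, design.y,
                              design.groups, nodes, logw)
        total = 0.0
        for g in np.unique(design.groups):
            m = design.groups == g

            def integrand(u):
                terms = _loglik_terms(beta, sigma, design.X[m], design.y[m],
                                      offset=u)
                return np.exp(terms.sum()) * norm.pdf(u, scale=tau)

            val, _ = integrate.quad(integrand, -10 * tau, 10 * tau, limit=200)
            total += np.log(val)
        assert gh == pytest.approx(total, abs=1e-6)


class TestFit:
    def test_uncensored_pooled_equals_ols(self, rng):
        # far-from-zero data: censoring never binds, so the Tobit MLE is
        # exactly the OLS/ML-normal solution
        n = 300
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta_true = np.array([50.0, 3.0])
        y = X @ beta_true + rng.normal(0, 2, n)
        assert (y > 0).all()
        design = TobitDesign(X=X, y=y, groups=np.arange(n), names=["const", "x"])
        fit = fit_tobit(design, random_intercept=False)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma_ml = float(np.sqrt(np.mean((y - X @ beta_ols) ** 2)))
        assert np.allclose(fit.beta.to_numpy(), beta_ols, atol=1e-6)
        assert fit.sigma == pytest.approx(sigma_ml, abs=1e-6)

    def test_all_censored_not_identifiable(self):
        design = TobitDesign(X=np.ones((4, 1)), y=np.zeros(4),
                             groups=np.arange(4), names=["const"])
        with pytest.raises(NonIdentifiableError):
            fit_tobit(design)

    def test_rank_deficient_design_rejected(self, rng):
        X = np.column_stack([np.ones(10), np.ones(10)])
        design = TobitDesign(X=X, y=np.abs(rng.normal(5, 1, 10)),
                             groups=np.arange(10), names=["a", "b"])
        with pytest.raises(DesignError):
            fit_tobit(design)

    def test_pooled_is_small_tau_limit(self, rng):
        # a random-intercept fit on data with no between-participant
        # variance drives tau toward 0 and reproduces the pooled estimates
        design = simulate_tobit([12.0, -5.0], 8.0, 0.0, 120, rng)
        pooled = fit_tobit(design, random_intercept=False)
        ri = fit_tobit(design, random_intercept=True, adaptive_quad=False)
        assert np.allclose(ri.beta.to_numpy(), pooled.beta.to_numpy(), atol=0.05)
        assert ri.sigma == pytest.approx(pooled.sigma, abs=0.1)
        assert ri.tau < 1.0

    def test_estimates_invariant_to_lambda_rescaling(self, rng):
        design = simulate_tobit([12.0, -5.0, -1.0], 8.0, 4.0, 80, rng)
        fit1 = fit_tobit(design, random_intercept=False)
        X2 = design.X.copy()
        X2[:, 2] *= 10.0
        design2 = TobitDesign(X=X2, y=design.y, groups=design.groups,
                              names=design.names)
        fit2 = fit_tobit(design2, random_intercept=False)
        assert fit2.beta["lambda_c"] == pytest.approx(
            fit1.beta["lambda_c"] / 10.0, rel=1e-4, abs=1e-6)
        assert fit2.beta["const"] == pytest.approx(fit1.beta["const"], rel=1e-4)
        assert fit2.sigma == pytest.approx(fit1.sigma, rel=1e-4)

    def test_recovers_random_intercept_sd(self, rng):
        design = simulate_tobit([14.0, -6.0, -1.0], 10.0, 5.0, 300, rng)
        fit = fit_tobit(design, random_intercept=True)
        assert fit.converged
        assert fit.tau == pytest.approx(5.0, abs=2.0)

    def test_matches_r_survreg_oracle(self, tmp_path, rng):
        # independent implementation check: R's survival::survreg fits the
        # same left-censored gaussian model (pooled)
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the survreg cross-check")
        design = simulate_tobit([10.0, -4.0], 8.0, 0.0, 40, rng)
        df = pd.DataFrame({"y": design.y, "cond": design.X[:, 1]})
        data_path = tmp_path / "tobit.csv"
        df.to_csv(data_path, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(survival))
            d <- read.csv("{data_path}")
            f <- survreg(Surv(y, y > 0, type = "left") ~ cond, data = d,
                         dist = "gaussian")
            cat(coef(f), f$scale, sep = "\\n")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        r_const, r_cond, r_scale = map(float, out.stdout.strip().split("\n"))
        fit = fit_tobit(design, random_intercept=False)
        assert fit.beta["const"] == pytest.approx(r_const, abs=1e-3)
        assert fit.beta["condition"] == pytest.approx(r_cond, abs=1e-3)
        assert fit.sigma == pytest.approx(r_scale, abs=1e-3)


class TestExpectedChoking:
    def _fit(self, sigma=1.0, beta=None):
        fit = cl.TobitFit(
            beta=pd.Series(beta if beta is not None else [0.0],
                           index=["const"][: 1 if beta is None else len(beta)]),
            sigma=sigma, tau=0.0,
            vcov=pd.DataFrame(np.eye(2), index=["const", "sigma"],
                              columns=["const", "sigma"]),
            loglik=0.0, converged=True, n_quad=0, n_obs=2, n_groups=1,
            random_intercept=False)
        return fit

    def test_value_at_zero_index(self):
        # xb = 0, sigma = 1 -> E(y|x) = phi(0)
        fit0 = self._fit(sigma=1.0, beta=[0.0])
        assert expected_choking(np.array([1.0]), fit0) == pytest.approx(
            0.3989422804, abs=1e-9)

    def test_small_sigma_limit_is_relu(self):
        fit = self._fit(sigma=1e-10, beta=[5.0])
        assert expected_choking(np.array([1.0]), fit) == pytest.approx(5.0,
                                                                       abs=1e-6)

    def test_matches_monte_carlo(self, rng):
        fit = self._fit(sigma=1.0, beta=[1.0])
        mc = np.maximum(rng.normal(1.0, 1.0, 2_000_000), 0.0).mean()
        val = expected_choking(np.array([1.0]), fit)
        assert val == pytest.approx(1.083332, abs=1e-4)
        assert val == pytest.approx(mc, abs=3e-3)

    def test_exceeds_relu_and_increases_with_sigma(self):
        for xb in (-2.0, 0.0, 3.0):
            vals = [expected_choking(np.array([1.0]),
                                     self._fit(sigma=s, beta=[xb]))
                    for s in (0.5, 1.0, 2.0)]
            assert all(v >= max(xb, 0.0) for v in vals)
            assert vals == sorted(vals)


class TestPartialEffect:
    def _fit(self, beta_cond):
        return cl.TobitFit(
            beta=pd.Series([10.0, beta_cond, 0.5, 0.1],
                           index=["const", "condition", "lambda_c",
                                  "condition_x_lambda_c"]),
            sigma=8.0, tau=0.0,
            vcov=pd.DataFrame(np.eye(5)), loglik=0.0, converged=True,
            n_quad=0, n_obs=2, n_groups=1, random_intercept=False)

    def test_zero_condition_coefficient_zero_effect(self):
        assert cl.partial_effect_reappraisal(self._fit(0.0)) == pytest.approx(0.0)

    def test_negative_coefficient_positive_effect(self):
        assert cl.partial_effect_reappraisal(self._fit(-6.0)) > 0.0

    def test_matches_monte_carlo_of_censored_mean(self, rng):
        fit = self._fit(-6.0)
        draws0 = np.maximum(rng.normal(10.0, 8.0, 1_000_000), 0.0).mean()
        draws1 = np.maximum(rng.normal(4.0, 8.0, 1_000_000), 0.0).mean()
        assert cl.partial_effect_reappraisal(fit) == pytest.approx(
            draws0 - draws1, abs=0.05)


class TestWald:
    def test_closed_form(self):
        fit = cl.TobitFit(
            beta=pd.Series([2.0], index=["b"]), sigma=1.0, tau=0.0,
            vcov=pd.DataFrame(np.diag([4.0, 1.0]), index=["b", "sigma"],
                              columns=["b", "sigma"]),
            loglik=0.0, converged=True, n_quad=0, n_obs=10, n_groups=10,
            random_intercept=False)
        table = wald_inference(fit)
        assert table.loc["b", "se"] == pytest.approx(2.0)
        assert table.loc["b", "z"] == pytest.approx(1.0)
        assert table.loc["b", "p"] == pytest.approx(0.3173, abs=1e-4)

    def test_se_shrinks_with_sample_size(self, rng):
        ses = []
        for n in (150, 600):  # 4x participants -> about half the SE
            design = simulate_tobit([12.0, -5.0], 8.0, 0.0, n, rng)
            fit = fit_tobit(design, random_intercept=False)
            ses.append(wald_inference(fit).loc["condition", "se"])
        ratio = ses[0] / ses[1]
        assert ratio == pytest.approx(2.0, rel=0.15)
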