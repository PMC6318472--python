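"""Left-censored Tobit regression with a random participant intercept.

The choking score y is nonnegative and piles up at zero, so it is
modelled through a latent normal index

    y*_it = x_it' beta + u_i + eps_it,   u_i ~ N(0, tau^2),
                                         eps_it ~ N(0, sigma^2),
    y_it  = y*_it if y*_it > 0 else 0,

where i indexes participants and t their (here, two) condition rows.
With ``random_intercept`` the likelihood marginalises u_i by
Gauss-Hermite quadrature; with tau fixed at zero the model reduces to
the pooled Tobit, whose log-likelihood is

    sum_{y>0} [ log phi((y - x'b)/s) - log s ] + sum_{y=0} log Phi(-x'b/s).

Expected censored outcomes use the standard partial-expectation formula
E(y|x) = Phi(x'b/s) x'b + s phi(x'b/s); the partial effect of reappraisal
is the drop in E(y|x) from the baseline to the reappraisal row for a
participant of mean loss aversion (conditional on u = 0, or marginalised
over u on request).

Covariances come from the inverse observed information (numerical
Hessian of the log-likelihood at the optimum); inference is Wald.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import norm

from .errors import DesignError, DomainError, InferenceError, NonIdentifiableError

__all__ = [
    "TobitDesign",
    "TobitFit",
    "make_design",
    "tobit_loglik",
    "fit_tobit",
    "expected_choking",
    "partial_effect_reappraisal",
    "wald_inference",
]


# ---------------------------------------------------------------------------
# design


@dataclass
class TobitDesign:
    """Regression frame: one row per (participant x condition)."""

    X: np.ndarray                 # n x p, first column all ones
    y: np.ndarray                 # n, >= 0 (0 = censored)
    groups: np.ndarray            # n, participant codes 0..G-1
    names: list[str]
    group_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.groups = np.asarray(self.groups, dtype=int)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise DesignError("X and y are not conformable")
        if np.any(self.y < 0):
            raise DesignError("choking scores must be >= 0 (censoring at zero)")

    @property
    def n_groups(self) -> int:
        return int(self.groups.max()) + 1 if len(self.groups) else 0


def make_design(
    scores: pd.DataFrame,
    lambdas: pd.Series,
    include_interaction: bool = True,
) -> TobitDesign:
    """Assemble the Tobit frame from choking scores and loss aversion.

    ``scores`` has columns participant_id, condition, choking_pp;
    ``lambdas`` maps participant_id -> lambda.  Covariates are an
    intercept, the condition code (baseline = 0, reappraisal = 1),
    mean-corrected loss aversion (lambda - mean over included
    participants) and, by default, their interaction.  Participants
    without a lambda are dropped listwise.
    """
    df = scores.copy()
    df = df[df["participant_id"].isin(lambdas.index)]
    if len(df) == 0:
        raise DesignError("no participants with both scores and loss aversion")
    lam = df["participant_id"].map(lambdas).astype(float)
    lam_centered = lam - lambdas.loc[sorted(df["participant_id"].unique())].mean()
    cond = (df["condition"] == "reappraisal").astype(float)
    cols = [np.ones(len(df)), cond.to_numpy(), lam_centered.to_numpy()]
    names = ["const", "condition", "lambda_c"]
    if include_interaction:
        cols.append(cond.to_numpy() * lam_centered.to_numpy())
        names.append("condition_x_lambda_c")
    pids = sorted(df["participant_id"].unique())
    codes = df["participant_id"].map({p: i for i, p in enumerate(pids)})
    return TobitDesign(
        X=np.column_stack(cols),
        y=df["choking_pp"].to_numpy(dtype=float),
        groups=codes.to_numpy(),
        names=names,
        group_ids=list(pids),
    )


# ---------------------------------------------------------------------------
# likelihood


def tobit_loglik(beta: np.ndarray, sigma: float, X: np.ndarray,
                 y: np.ndarray) -> float:
    """Pooled Tobit log-likelihood (no random intercept)."""
    return float(_loglik_terms(np.asarray(beta, float), sigma,
                               np.asarray(X, float), np.asarray(y, float)).sum())


def _loglik_terms(beta, sigma, X, y, offset=0.0):
    """Per-observation censored-normal log densities; offset shifts the index."""
    if sigma <= 0:
        raise DomainError("sigma must be positive")
    xb = X @ beta + offset
    cens = y <= 0
    out = np.empty(len(y))
    out[~cens] = norm.logpdf((y[~cens] - xb[~cens]) / sigma) - np.log(sigma)
    out[cens] = norm.logcdf(-xb[cens] / sigma)
    return out


def _marginal_loglik(beta, sigma, tau, X, y, groups, nodes, logw):
    """Random-intercept marginal log-likelihood via Gauss-Hermite.

    For each participant, log integral over u ~ N(0, tau^2) of the product
    of censored-normal densities, evaluated at u_k = sqrt(2) tau a_k with
    weights w_k / sqrt(pi).
    """
    xb = X @ beta
    u = np.sqrt(2.0) * tau * nodes                    # (K,)
    idx = xb[:, None] + u[None, :]                    # (n, K)
    cens = y <= 0
    terms = np.empty_like(idx)
    terms[cens] = norm.logcdf(-idx[cens] / sigma)
    terms[~cens] = norm.logpdf((y[~cens, None] - idx[~cens]) / sigma) - np.log(sigma)
    G = int(groups.max()) + 1
    per_group = np.zeros((G, len(u)))
    np.add.at(per_group, groups, terms)
    return float(logsumexp(per_group + logw[None, :], axis=1).sum())


def _pack_loglik(design: TobitDesign, random_intercept: bool, n_quad: int):
    X, y, groups = design.X, design.y, design.groups
    if random_intercept:
        nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
        logw = np.log(weights) - 0.5 * np.log(np.pi)

        def loglik(theta):
            p = X.shape[1]
            beta, log_sigma, log_tau = theta[:p], theta[p], theta[p + 1]
            return _marginal_loglik(beta, np.exp(log_sigma), np.exp(log_tau),
                                    X, y, groups, nodes, logw)
    else:
        def loglik(theta):
            p = X.shape[1]
            beta, log_sigma = theta[:p], theta[p]
            return float(_loglik_terms(beta, np.exp(log_sigma), X, y).sum())
    return loglik


# ---------------------------------------------------------------------------
# fit


@dataclass
class TobitFit:
    """Fitted Tobit model.

    beta is indexed by covariate name; sigma is the latent residual SD and
    tau the random-intercept SD (0 for the pooled model).  ``vcov`` covers
    (beta..., sigma[, tau]) from the inverse observed information.
    """

    beta: pd.Series
    sigma: float
    tau: float
    vcov: pd.DataFrame
    loglik: float
    converged: bool
    n_quad: int
    n_obs: int
    n_groups: int
    random_intercept: bool
    names: list[str] = field(default_factory=list)

    @property
    def param_names(self) -> list[str]:
        extra = ["sigma"] + (["tau"] if self.random_intercept else [])
        return list(self.beta.index) + extra


def _init_theta(design: TobitDesign, random_intercept: bool,
                rng: np.random.Generator, jitter: float = 0.0) -> np.ndarray:
    """OLS-on-uncensored initialisation with optional jitter for restarts."""
    X, y = design.X, design.y
    unc = y > 0
    beta0, *_ = np.linalg.lstsq(X[unc], y[unc], rcond=None)
    resid = y[unc] - X[unc] @ beta0
    sigma0 = max(float(np.std(resid)), 1e-2)
    theta = list(beta0) + [np.log(sigma0)]
    if random_intercept:
        df = pd.DataFrame({"g": design.groups[unc], "r": resid})
        tau0 = float(df.groupby("g")["r"].mean().std())
        if not np.isfinite(tau0) or tau0 < 1e-2:
            tau0 = sigma0 / 2
        theta.append(np.log(tau0))
    theta = np.asarray(theta, float)
    if jitter > 0:
        theta = theta + rng.normal(0.0, jitter, size=len(theta))
    return theta


def fit_tobit(
    design: TobitDesign,
    random_intercept: bool = True,
    n_quad: int = 32,
    init: np.ndarray | None = None,
    seed: int = 0,
    max_restarts: int = 3,
    adaptive_quad: bool = True,
) -> TobitFit:
    """Maximum-likelihood Tobit fit.

    With ``random_intercept`` the participant intercept u_i ~ N(0, tau^2)
    is integrated out by Gauss-Hermite quadrature (``n_quad`` nodes,
    doubled until the log-likelihood is stable to 1e-6 when
    ``adaptive_quad``); otherwise a pooled Tobit is fitted.  sigma and tau
    are optimised on log scale; on non-convergence the optimiser restarts
    (up to ``max_restarts``, seeded jitter) and a still-unconverged fit is
    returned flagged, not raised.
    """
    X, y = design.X, design.y
    n_unc = int((y > 0).sum())
    if n_unc == 0:
        raise NonIdentifiableError("all observations censored at zero")
    if n_unc < 2:
        raise NonIdentifiableError(
            "fewer than 2 uncensored observations; scale not identifiable")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design matrix is rank deficient")

    rng = np.random.default_rng(seed)
    loglik = _pack_loglik(design, random_intercept, n_quad)
    neg = lambda th: -loglik(th)

    res = None
    for attempt in range(max_restarts + 1):
        theta0 = (np.asarray(init, float) if (init is not None and attempt == 0)
                  else _init_theta(design, random_intercept, rng,
                                   jitter=0.2 * attempt))
        cand = optimize.minimize(neg, theta0, method="BFGS",
                                 options={"gtol": 1e-7, "maxiter": 500})
        if res is None or cand.fun < res.fun:
            res = cand
        if res.success:
            break
    converged = bool(res.success or np.linalg.norm(res.jac) < 1e-3)

    # refine the quadrature until the log-likelihood is stable
    if random_intercept and adaptive_quad:
        while n_quad < 256:
            ll_fine = _pack_loglik(design, True, 2 * n_quad)(res.x)
            if abs(ll_fine - (-res.fun)) <= 1e-6:
                break
            n_quad *= 2
            loglik = _pack_loglik(design, True, n_quad)
            neg = lambda th: -loglik(th)
            res = optimize.minimize(neg, res.x, method="BFGS",
                                    options={"gtol": 1e-7, "maxiter": 500})
            converged = bool(res.success or np.linalg.norm(res.jac) < 1e-3)

    p = X.shape[1]
    beta = res.x[:p]
    sigma = float(np.exp(res.x[p]))
    tau = float(np.exp(res.x[p + 1])) if random_intercept else 0.0
    vcov = _observed_information_vcov(design, random_intercept, n_quad,
                                      beta, sigma, tau)
    names = design.names + ["sigma"] + (["tau"] if random_intercept else [])
    if not converged:
        warnings.warn("Tobit optimiser did not converge; fit flagged",
                      stacklevel=2)
    return TobitFit(
        beta=pd.Series(beta, index=design.names),
        sigma=sigma,
        tau=tau,
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        loglik=float(-res.fun),
        converged=converged,
        n_quad=n_quad if random_intercept else 0,
        n_obs=len(y),
        n_groups=design.n_groups,
        random_intercept=random_intercept,
        names=names,
    )


def _observed_information_vcov(design, random_intercept, n_quad,
                               beta, sigma, tau):
    """Inverse numerical Hessian of -loglik in the natural parameters."""
    X, y, groups = design.X, design.y, design.groups
    if random_intercept:
        nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
        logw = np.log(weights) - 0.5 * np.log(np.pi)

        def f(params):
            p = X.shape[1]
            return _marginal_loglik(params[:p], params[p], params[p + 1],
                                    X, y, groups, nodes, logw)
        x0 = np.concatenate([beta, [sigma, tau]])
    else:
        def f(params):
            p = X.shape[1]
            return float(_loglik_terms(params[:p], params[p], X, y).sum())
        x0 = np.concatenate([beta, [sigma]])
    H = _numerical_hessian(f, x0)
    info = -H
    try:
        vcov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(info)
    return 0.5 * (vcov + vcov.T)


def _numerical_hessian(f, x0: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; steps scaled to parameter magnitude."""
    k = len(x0)
    h = rel_step * np.maximum(1.0, np.abs(x0))
    H = np.empty((k, k))
    f0 = f(x0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej)
                    - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# expected outcomes and partial effects


def expected_choking(xrow: np.ndarray, fit: TobitFit,
                     marginalize: bool = False, n_quad: int = 64) -> float:
    """Expected censored outcome E(y|x) = Phi(x'b/s) x'b + s phi(x'b/s).

    By default the expectation is conditional on u = 0 (the average
    participant); with ``marginalize`` it is integrated over the fitted
    random-intercept distribution by quadrature.
    """
    xb = float(np.dot(np.asarray(xrow, float), fit.beta.to_numpy()))
    if not np.isfinite(xb):
        raise DomainError("non-finite linear predictor")
    if marginalize and fit.tau > 0:
        nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
        u = np.sqrt(2.0) * fit.tau * nodes
        vals = _censored_mean(xb + u, fit.sigma)
        return float(np.sum(weights / np.sqrt(np.pi) * vals))
    return float(_censored_mean(np.array([xb]), fit.sigma)[0])


def _censored_mean(xb: np.ndarray, sigma: float) -> np.ndarray:
    z = xb / sigma
    return norm.cdf(z) * xb + sigma * norm.pdf(z)


def partial_effect_reappraisal(fit: TobitFit, lambda_c: float = 0.0,
                               marginalize: bool = False) -> float:
    """Drop in expected choking from baseline to reappraisal.

    Evaluated at mean-corrected loss aversion ``lambda_c`` (0 = the
    average participant): E(y | condition = 0) - E(y | condition = 1).
    Positive values mean reappraisal reduces expected choking.
    """
    if "condition" not in fit.beta.index:
        raise DomainError("fit has no condition coefficient")
    rows = {}
    for cond in (0.0, 1.0):
        x = []
        for name in fit.beta.index:
            if name == "const":
                x.append(1.0)
            elif name == "condition":
                x.append(cond)
            elif name == "lambda_c":
                x.append(lambda_c)
            elif name == "condition_x_lambda_c":
                x.append(cond * lambda_c)
            else:
                raise DomainError(f"unknown covariate {name!r}")
        rows[cond] = expected_choking(np.array(x), fit, marginalize=marginalize)
    return rows[0.0] - rows[1.0]


def wald_inference(fit: TobitFit) -> pd.DataFrame:
    """Wald table: estimate, SE, z and two-sided normal p per parameter."""
    var = np.diag(fit.vcov.to_numpy())
    if np.any(var < -1e-10):
        raise InferenceError(
            "covariance matrix is not positive semidefinite; "
            f"negative variances for {list(fit.vcov.index[var < 0])}")
    est = np.concatenate([fit.beta.to_numpy(),
                          [fit.sigma] + ([fit.tau] if fit.random_intercept else [])])
    se = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
    pvals = 2 * norm.sf(np.abs(z))
    return pd.DataFrame(
        {"estimate": est, "se": se, "z": z, "p": pvals},
        index=fit.vcov.index,
    )
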