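"""Estimation procedures for clustered binary outcomes.

Four fitters share one interface (a :class:`ClusteredDataset` plus a list of
covariate names) and return a :class:`FitResult`:

* ``fit_logistic`` -- ordinary maximum-likelihood logistic regression that
  ignores the clustering entirely (conditional coefficients, model-based
  standard errors);
* ``fit_glmm_pql`` -- random-intercept logistic regression by penalised
  quasi-likelihood: iterative working-variate linearisation with a REML
  variance-component update on the working linear mixed model;
* ``fit_glmm_agq`` -- random-intercept logistic regression by maximising the
  exact marginal likelihood, with each cluster's integral over the random
  intercept evaluated by adaptive Gauss-Hermite quadrature (default 5
  nodes; 1 node gives the Laplace approximation);
* ``fit_gee_exchangeable`` -- generalised estimating equations with an
  exchangeable working correlation and robust sandwich standard errors
  (marginal, population-average coefficients).

``apply_divergence_filter`` implements the study's bookkeeping rule that a
fit reporting any coefficient above 1000 in absolute value is treated as
non-converged, with all its estimates discarded.

Only cluster sizes 1 and 2 are supported; larger clusters raise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Any

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit
from statsmodels.tools.numdiff import approx_hess

from .synthetic_data import ClusteredDataset, ValidationError

__all__ = [
    "FitResult",
    "QuadratureRule",
    "fit_logistic",
    "fit_glmm_pql",
    "fit_glmm_agq",
    "fit_gee_exchangeable",
    "apply_divergence_filter",
    "marginal_loglik",
    "DIVERGENCE_THRESHOLD",
]

DIVERGENCE_THRESHOLD = 1000.0
_LOG_SIGMA_BOUNDS = (-10.0, 5.0)


@dataclass(frozen=True)
class QuadratureRule:
    """Gauss-Hermite abscissae and log-weights (physicists' convention)."""

    n_nodes: int = 5
    adaptive: bool = True

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ValidationError("quadrature needs at least one node")

    @property
    def nodes_weights(self) -> tuple[np.ndarray, np.ndarray]:
        return _hermgauss_cached(self.n_nodes)


@lru_cache(maxsize=None)
def _hermgauss_cached(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    t, w = np.polynomial.hermite.hermgauss(n_nodes)
    return t, np.log(w)


@dataclass(frozen=True)
class FitResult:
    """Coefficients, standard errors and bookkeeping for one model fit."""

    method: str
    estimates: dict[str, float]
    standard_errors: dict[str, float]
    variance_estimate: float | None
    converged: bool
    n_iterations: int
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def coefficient_vector(self, names) -> np.ndarray:
        return np.array([self.estimates[n] for n in names], dtype=float)

    def to_json_dict(self) -> dict[str, Any]:
        return {
            "method": self.method,
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "standard_errors": {k: float(v) for k, v in self.standard_errors.items()},
            "variance_estimate": (
                None if self.variance_estimate is None else float(self.variance_estimate)
            ),
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iterations),
            "diagnostics": {k: str(v) for k, v in self.diagnostics.items()},
        }


def _nonconverged(method: str, names, note: str, variance=None) -> FitResult:
    nan = float("nan")
    return FitResult(
        method=method,
        estimates={n: nan for n in names},
        standard_errors={n: nan for n in names},
        variance_estimate=variance,
        converged=False,
        n_iterations=0,
        diagnostics={"note": note},
    )


# ---------------------------------------------------------------------------
# data preparation


def _design(frame: pd.DataFrame, covariates) -> tuple[np.ndarray, np.ndarray, list[str]]:
    missing = [c for c in covariates if c not in frame.columns]
    if missing:
        raise ValidationError(f"covariates missing from dataset: {missing}")
    X = np.column_stack(
        [np.ones(len(frame))] + [frame[c].to_numpy(dtype=float) for c in covariates]
    )
    y = frame["y"].to_numpy(dtype=float)
    return X, y, ["intercept", *list(covariates)]


def _split_clusters(dataset: ClusteredDataset, covariates):
    """Sort rows by (cluster, member) and split into singleton/pair arrays."""
    frame = dataset.frame.sort_values(["cluster_id", "member"], kind="mergesort")
    X, y, names = _design(frame, covariates)
    sizes = frame.groupby("cluster_id", sort=False).size().to_numpy()
    if (sizes > 2).any():
        raise ValidationError("cluster sizes greater than 2 are not supported")
    row_size = np.repeat(sizes, sizes)
    s_mask = row_size == 1
    Xs, ys = X[s_mask], y[s_mask]
    Xp = X[~s_mask].reshape(-1, 2, X.shape[1])
    yp = y[~s_mask].reshape(-1, 2)
    return Xs, ys, Xp, yp, names, frame


# ---------------------------------------------------------------------------
# logistic regression


def fit_logistic(dataset: ClusteredDataset, covariates) -> FitResult:
    """Maximum-likelihood logistic regression ignoring the clustering."""
    X, y, names = _design(dataset.frame, covariates)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except Exception as exc:  # separation, singular Hessian, ...
        return _nonconverged("logistic", names, f"fit failed: {exc}")
    params, bse = np.asarray(res.params), np.asarray(res.bse)
    ok = bool(res.mle_retvals.get("converged", False))
    ok = ok and np.isfinite(params).all() and np.isfinite(bse).all() and (bse > 0).all()
    return FitResult(
        method="logistic",
        estimates=dict(zip(names, params)),
        standard_errors=dict(zip(names, bse)),
        variance_estimate=None,
        converged=ok,
        n_iterations=int(res.mle_retvals.get("iterations", 0)),
        diagnostics={"loglik": float(res.llf)},
    )


def _logistic_start(dataset, covariates, names):
    start = fit_logistic(dataset, covariates)
    if start.converged:
        return start.coefficient_vector(names), start
    return np.zeros(len(names)), start


# ---------------------------------------------------------------------------
# PQL


def _pql_blocks(sigma2, ws, wp):
    """Per-cluster working covariance pieces V = W^-1 + sigma2 * J."""
    vs = 1.0 / ws + sigma2  # singletons, (ns,)
    ia = 1.0 / wp[:, 0] + sigma2
    ib = 1.0 / wp[:, 1] + sigma2
    det = ia * ib - sigma2**2
    alpha = ib / det
    delta = ia / det
    gamma = -sigma2 / det
    return vs, ia, ib, det, alpha, delta, gamma


def _pql_normal_equations(sigma2, Xs, zs, ws, Xp, zp, wp):
    vs, ia, ib, det, alpha, delta, gamma = _pql_blocks(sigma2, ws, wp)
    p = Xs.shape[1] if Xs.size else Xp.shape[2]
    A = np.zeros((p, p))
    b = np.zeros(p)
    if len(Xs):
        Xw = Xs / vs[:, None]
        A += Xs.T @ Xw
        b += Xw.T @ zs
    if len(Xp):
        Xa, Xb = Xp[:, 0, :], Xp[:, 1, :]
        A += np.einsum("n,np,nq->pq", alpha, Xa, Xa)
        A += np.einsum("n,np,nq->pq", delta, Xb, Xb)
        cross = np.einsum("n,np,nq->pq", gamma, Xa, Xb)
        A += cross + cross.T
        b += Xa.T @ (alpha * zp[:, 0] + gamma * zp[:, 1])
        b += Xb.T @ (gamma * zp[:, 0] + delta * zp[:, 1])
    return A, b, (vs, det, alpha, delta, gamma)

def _pql_reml(sigma2, Xs, zs, ws, Xp, zp, wp):
    """Negative restricted log-likelihood of the working linear mixed model."""
    A, b, (vs, det, alpha, delta, gamma) = _pql_normal_equations(
        sigma2, Xs, zs, ws, Xp, zp, wp
    )
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.inf
    logdet = 0.0
    quad = 0.0
    if len(Xs):
        rs = zs - Xs @ beta
        logdet += np.log(vs).sum()
        quad += (rs**2 / vs).sum()
    if len(Xp):
        ra = zp[:, 0] - Xp[:, 0, :] @ beta
        rb = zp[:, 1] - Xp[:, 1, :] @ beta
        logdet += np.log(det).sum()
        quad += (alpha * ra**2 + delta * rb**2 + 2 * gamma * ra * rb).sum()
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    return 0.5 * (logdet + logdet_A + quad)


def fit_glmm_pql(
    dataset: ClusteredDataset,
    covariates,
    tol: float = 1e-6,
    max_iter: int = 50,
    sigma2_fixed: float | None = None,
) -> FitResult:
    """Random-intercept logistic regression by penalised quasi-likelihood.

    Alternates (a) the working response ``z = eta + (y - p)/(p(1-p))`` with
    weights ``w = p(1-p)``, (b) a weighted mixed-model solve for the fixed
    effects and cluster BLUPs, and (c) a REML update of the random-intercept
    variance on the working model, until the largest parameter change drops
    below ``tol``.  ``sigma2_fixed`` pins the variance (0 reduces the
    procedure to plain IRLS and hence the logistic MLE).
    """
    try:
        Xs, ys, Xp, yp, names, _ = _split_clusters(dataset, covariates)
    except ValidationError:
        raise
    p = len(names)
    beta = np.zeros(p)
    u_s = np.zeros(len(Xs))
    u_p = np.zeros(len(Xp))
    sigma2 = float(sigma2_fixed) if sigma2_fixed is not None else 0.5
    converged = False
    n_iter = 0
    A = np.eye(p)
    for n_iter in range(1, max_iter + 1):
        eta_s = Xs @ beta + u_s if len(Xs) else np.empty(0)
        eta_p = Xp @ beta + u_p[:, None] if len(Xp) else np.empty((0, 2))
        mu_s = np.clip(expit(eta_s), 1e-10, 1 - 1e-10)
        mu_p = np.clip(expit(eta_p), 1e-10, 1 - 1e-10)
        ws = np.clip(mu_s * (1 - mu_s), 1e-10, None)
        wp = np.clip(mu_p * (1 - mu_p), 1e-10, None)
        zs = eta_s + (ys - mu_s) / ws
        zp = eta_p + (yp - mu_p) / wp

        if sigma2_fixed is None:
            opt = minimize_scalar(
                _pql_reml,
                bounds=(0.0, 100.0),
                args=(Xs, zs, ws, Xp, zp, wp),
                method="bounded",
                options={"xatol": 1e-10},
            )
            sigma2_new = float(opt.x)
            # the bounded minimiser never tries the boundary itself
            if _pql_reml(0.0, Xs, zs, ws, Xp, zp, wp) <= opt.fun:
                sigma2_new = 0.0
        else:
            sigma2_new = float(sigma2_fixed)

        A, b, (vs, det, alpha, delta, gamma) = _pql_normal_equations(
            sigma2_new, Xs, zs, ws, Xp, zp, wp
        )
        try:
            beta_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return _nonconverged("glmm_pql", names, "singular working mixed-model solve")
        if len(Xs):
            rs = zs - Xs @ beta_new
            u_s = sigma2_new * rs / vs
        if len(Xp):
            ra = zp[:, 0] - Xp[:, 0, :] @ beta_new
            rb = zp[:, 1] - Xp[:, 1, :] @ beta_new
            u_p = sigma2_new * ((alpha + gamma) * ra + (gamma + delta) * rb)

        change = max(
            float(np.max(np.abs(beta_new - beta))), abs(sigma2_new - sigma2)
        )
        beta, sigma2 = beta_new, sigma2_new
        if not np.isfinite(beta).all():
            return _nonconverged("glmm_pql", names, "non-finite working estimates")
        if change < tol:
            converged = True
            break

    try:
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return _nonconverged("glmm_pql", names, "singular information matrix")
    bse = np.sqrt(np.clip(np.diag(cov), 0, None))
    converged = converged and bool(np.isfinite(bse).all() and (bse > 0).all())
    diagnostics: dict[str, Any] = {}
    if sigma2 < 1e-8:
        diagnostics["variance_boundary"] = True
    return FitResult(
        method="glmm_pql",
        estimates=dict(zip(names, beta)),
        standard_errors=dict(zip(names, bse)),
        variance_estimate=float(sigma2),
        converged=converged,
        n_iterations=n_iter,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# adaptive Gauss-Hermite


def _bernoulli_loglik(eta, y):
    # y*eta - log(1 + exp(eta)), stable for large |eta|
    return y * eta - np.logaddexp(0.0, eta)


def _group_agq_loglik(X3, y2, beta, sigma, t, logw, want_grad=False):
    """Per-cluster marginal log-likelihood contributions, summed.

    ``X3`` has shape (n_clusters, m, p) and ``y2`` (n_clusters, m) for a
    common cluster size m.  The integral over the random intercept is
    evaluated by Gauss-Hermite quadrature recentred at each cluster's
    posterior mode and rescaled by the curvature there.  With
    ``want_grad`` the same node sweep also yields the score with respect
    to ``beta`` and ``log sigma`` (holding the adaptive centring fixed,
    exact up to the quadrature truncation error).
    """
    p = X3.shape[2]
    if len(X3) == 0:
        return (0.0, np.zeros(p), 0.0) if want_grad else 0.0
    eta0 = X3 @ beta  # (n, m)
    inv_s2 = 1.0 / sigma**2
    u = np.zeros(len(X3))
    for _ in range(60):
        pr = expit(eta0 + u[:, None])
        grad = (y2 - pr).sum(axis=1) - u * inv_s2
        hess = (pr * (1 - pr)).sum(axis=1) + inv_s2
        step = np.clip(grad / hess, -10.0, 10.0)
        u += step
        if np.max(np.abs(step)) < 1e-11:
            break
    pr = expit(eta0 + u[:, None])
    h = (pr * (1 - pr)).sum(axis=1) + inv_s2
    s = 1.0 / np.sqrt(h)
    uk = u[:, None] + math.sqrt(2.0) * s[:, None] * t[None, :]  # (n, K)
    eta = eta0[:, None, :] + uk[:, :, None]  # (n, K, m)
    resid = y2[:, None, :] - expit(eta)  # (n, K, m)
    ll_y = (y2[:, None, :] * eta - np.logaddexp(0.0, eta)).sum(axis=2)  # (n, K)
    ll_u = -0.5 * uk**2 * inv_s2 - math.log(sigma) - 0.5 * math.log(2 * math.pi)
    integrand = logw[None, :] + t[None, :] ** 2 + ll_y + ll_u
    # inline log-sum-exp over nodes (axis 1)
    peak = integrand.max(axis=1)
    expd = np.exp(integrand - peak[:, None])
    norm = expd.sum(axis=1)
    li = np.log(math.sqrt(2.0) * s) + peak + np.log(norm)
    total = float(li.sum())
    if not want_grad:
        return total
    omega = expd / norm[:, None]  # posterior node weights, (n, K)
    grad_beta = np.einsum("nk,nkm,nmp->p", omega, resid, X3)
    grad_logsigma = float((omega * (uk**2 * inv_s2 - 1.0)).sum())
    return total, grad_beta, grad_logsigma


def _agq_loglik_arrays(
    Xs, ys, Xp, yp, beta, sigma2, rule: QuadratureRule, want_grad: bool = False
):
    p = len(beta)
    if sigma2 < 1e-16:
        total, grad = 0.0, np.zeros(p)
        if len(Xs):
            eta = Xs @ beta
            total += float(_bernoulli_loglik(eta, ys).sum())
            grad += (ys - expit(eta)) @ Xs
        if len(Xp):
            eta = Xp @ beta
            total += float(_bernoulli_loglik(eta, yp).sum())
            grad += np.einsum("nm,nmp->p", yp - expit(eta), Xp)
        return (total, grad, 0.0) if want_grad else total
    t, logw = rule.nodes_weights
    sigma = math.sqrt(sigma2)
    total, grad, grad_s = 0.0, np.zeros(p), 0.0
    for X3, y2 in ((Xs[:, None, :], ys[:, None]), (Xp, yp)):
        out = _group_agq_loglik(X3, y2, beta, sigma, t, logw, want_grad=want_grad)
        if want_grad:
            total, grad, grad_s = total + out[0], grad + out[1], grad_s + out[2]
        else:
            total += out
    return (total, grad, grad_s) if want_grad else total


def marginal_loglik(
    dataset: ClusteredDataset,
    covariates,
    params,
    sigma2: float,
    n_nodes: int = 5,
) -> float:
    """Marginal log-likelihood of a random-intercept logistic model.

    ``params`` maps coefficient names (including ``"intercept"``) to values.
    Exposed separately so the quadrature can be checked against brute-force
    numerical integration.
    """
    Xs, ys, Xp, yp, names, _ = _split_clusters(dataset, covariates)
    beta = np.array([params[n] for n in names], dtype=float)
    if sigma2 < 0:
        raise ValidationError("variance must be non-negative")
    return _agq_loglik_arrays(Xs, ys, Xp, yp, beta, sigma2, QuadratureRule(n_nodes))


def fit_glmm_agq(
    dataset: ClusteredDataset,
    covariates,
    rule: QuadratureRule | None = None,
    sigma2_fixed: float | None = None,
    maxiter: int = 200,
) -> FitResult:
    """Random-intercept logistic regression by adaptive Gauss-Hermite ML.

    The marginal likelihood is maximised over ``(beta, log sigma)`` by
    L-BFGS-B; the random-intercept standard deviation is kept on the log
    scale with a lower bound, and a fit pinned at that bound is reported as
    a variance estimate of 0 with a boundary diagnostic rather than a
    failure.  Standard errors come from the inverse of a numerically
    differentiated observed information matrix.
    """
    rule = rule or QuadratureRule()
    Xs, ys, Xp, yp, names, _ = _split_clusters(dataset, covariates)
    p = len(names)
    beta0, start_fit = _logistic_start(dataset, covariates, names)

    # standardise columns internally so the optimiser sees O(1) coordinates
    # (birthweight in grams would otherwise dominate the conditioning)
    all_X = np.vstack([Xs, Xp.reshape(-1, p)]) if len(Xp) else Xs
    scales = all_X.std(axis=0)
    scales[scales < 1e-12] = 1.0
    scales[0] = 1.0  # intercept column
    Xs = Xs / scales
    Xp = Xp / scales if len(Xp) else Xp
    beta0 = beta0 * scales

    def nll_beta(beta, sigma2):
        val = _agq_loglik_arrays(Xs, ys, Xp, yp, beta, sigma2, rule)
        return -val if np.isfinite(val) else 1e300

    if sigma2_fixed is not None:
        if sigma2_fixed < 0:
            raise ValidationError("variance must be non-negative")

        def nll_beta_grad(beta):
            val, grad, _ = _agq_loglik_arrays(
                Xs, ys, Xp, yp, beta, float(sigma2_fixed), rule, want_grad=True
            )
            if not np.isfinite(val):
                return 1e300, np.zeros(p)
            return -val, -grad

        res = minimize(
            nll_beta_grad,
            beta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-8},
        )
        beta_hat = res.x
        sigma2_hat = float(sigma2_fixed)
        boundary = sigma2_hat == 0.0
        log_sigma_hat = None
    else:
        def nll_grad(theta):
            val, grad_b, grad_s = _agq_loglik_arrays(
                Xs, ys, Xp, yp, theta[:p], math.exp(2.0 * theta[p]), rule, want_grad=True
            )
            if not np.isfinite(val):
                return 1e300, np.zeros(p + 1)
            return -val, -np.append(grad_b, grad_s)

        def nll(theta):
            return nll_beta(theta[:p], math.exp(2.0 * theta[p]))

        x0 = np.append(beta0, 0.0)
        bounds = [(None, None)] * p + [_LOG_SIGMA_BOUNDS]
        res = minimize(
            nll_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-7},
        )
        if not res.success:
            # the analytic score holds the adaptive centring fixed, which can
            # abort the line search close to the optimum; polish with
            # finite-difference gradients from the current point
            polish = minimize(
                nll,
                res.x,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-6},
            )
            if polish.fun <= res.fun + 1e-10:
                res = polish
        beta_hat = res.x[:p]
        log_sigma_hat = float(res.x[p])
        boundary = log_sigma_hat <= _LOG_SIGMA_BOUNDS[0] + 1e-6
        sigma2_hat = 0.0 if boundary else math.exp(2.0 * log_sigma_hat)

    diagnostics: dict[str, Any] = {"loglik": -float(res.fun)}
    if boundary:
        diagnostics["variance_boundary"] = True

    # observed information at the optimum
    variance_se = None
    try:
        if boundary or sigma2_fixed is not None:
            H = approx_hess(beta_hat, lambda b: nll_beta(b, sigma2_hat))
            cov = np.linalg.inv(H)
            bse = np.sqrt(np.diag(cov))
        else:
            theta_hat = np.append(beta_hat, log_sigma_hat)
            H = approx_hess(theta_hat, lambda th: nll_beta(th[:p], math.exp(2.0 * th[p])))
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            if (d <= 0).any():
                raise np.linalg.LinAlgError("observed information not positive definite")
            bse = np.sqrt(d[:p])
            variance_se = 2.0 * sigma2_hat * math.sqrt(d[p])
    except np.linalg.LinAlgError as exc:
        out = _nonconverged("glmm_agq", names, f"information matrix failure: {exc}")
        return replace(out, variance_estimate=float(sigma2_hat), diagnostics={**diagnostics, **out.diagnostics})

    if variance_se is not None:
        diagnostics["variance_se"] = float(variance_se)
    beta_out = beta_hat / scales
    bse_out = bse / scales
    ok = bool(res.success) and np.isfinite(beta_out).all()
    ok = ok and bool(np.isfinite(bse_out).all() and (bse_out > 0).all())
    return FitResult(
        method="glmm_agq",
        estimates=dict(zip(names, beta_out)),
        standard_errors=dict(zip(names, bse_out)),
        variance_estimate=float(sigma2_hat),
        converged=ok,
        n_iterations=int(res.nit),
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# GEE


def fit_gee_exchangeable(
    dataset: ClusteredDataset,
    covariates,
    tol: float = 1e-9,
    max_iter: int = 60,
) -> FitResult:
    """GEE with logit link, exchangeable working correlation, sandwich SEs.

    Solves the estimating equations by Fisher scoring with closed-form
    1x1 / 2x2 working-covariance blocks.  The working correlation is
    re-estimated each iteration by moments from within-pair standardised
    residual cross-products (Pearson-scale moment estimator with the
    number-of-parameters degrees-of-freedom correction); singleton
    clusters contribute nothing to it, and if the data contain no pair at
    all it is fixed at zero (independence) and flagged in the
    diagnostics.  Standard errors are the robust sandwich estimates with
    no small-sample correction.  Estimates carry a marginal
    (population-average) interpretation.
    """
    Xs, ys, Xp, yp, names, _ = _split_clusters(dataset, covariates)
    p = len(names)
    n_obs = len(ys) + 2 * len(yp)
    n_pairs = len(Xp)
    no_pairs = n_pairs == 0
    beta = np.zeros(p)
    rho = 0.0
    converged = False
    n_iter = 0
    B = np.eye(p)
    try:
        for n_iter in range(1, max_iter + 1):
            mu_s = expit(Xs @ beta) if len(Xs) else np.empty(0)
            mu_p = expit(Xp @ beta) if n_pairs else np.empty((0, 2))
            a_s = np.clip(mu_s * (1 - mu_s), 1e-10, None)
            a_p = np.clip(mu_p * (1 - mu_p), 1e-10, None)
            r_s = ys - mu_s
            r_p = yp - mu_p

            if not no_pairs:
                # moment update of the working correlation from pairs only
                pr_s = r_s / np.sqrt(a_s)
                pr_p = r_p / np.sqrt(a_p)
                scale = (np.sum(pr_s**2) + np.sum(pr_p**2)) / max(n_obs - p, 1)
                cross = float(np.sum(pr_p[:, 0] * pr_p[:, 1])) / scale
                # parameter-count df correction only when there are enough
                # pairs for it to make sense
                denom = n_pairs - p if n_pairs > p else n_pairs
                rho = float(np.clip(cross / denom, -0.99, 0.99))

            B = np.zeros((p, p))
            score = np.zeros(p)
            if len(Xs):
                B += (Xs * a_s[:, None]).T @ Xs
                score += r_s @ Xs
            if not no_pairs:
                w = 1.0 / (1.0 - rho**2)
                sa, sb = a_p[:, 0], a_p[:, 1]
                gm = np.sqrt(sa * sb)
                Xa, Xb = Xp[:, 0, :], Xp[:, 1, :]
                B += w * np.einsum("n,np,nq->pq", sa, Xa, Xa)
                B += w * np.einsum("n,np,nq->pq", sb, Xb, Xb)
                cross_B = np.einsum("n,np,nq->pq", -w * rho * gm, Xa, Xb)
                B += cross_B + cross_B.T
                ca = w * (r_p[:, 0] - rho * np.sqrt(sa / sb) * r_p[:, 1])
                cb = w * (r_p[:, 1] - rho * np.sqrt(sb / sa) * r_p[:, 0])
                score += ca @ Xa + cb @ Xb
            step = np.linalg.solve(B, score)
            beta = beta + step
            if not np.isfinite(beta).all():
                return _nonconverged("gee", names, "non-finite estimates")
            if np.max(np.abs(step)) < tol:
                converged = True
                break

        # robust sandwich covariance at the solution
        M = np.zeros((p, p))
        mu_s = expit(Xs @ beta) if len(Xs) else np.empty(0)
        if len(Xs):
            g_s = Xs * (ys - mu_s)[:, None]
            M += g_s.T @ g_s
        if not no_pairs:
            mu_p = expit(Xp @ beta)
            a_p = np.clip(mu_p * (1 - mu_p), 1e-10, None)
            r_p = yp - mu_p
            sa, sb = a_p[:, 0], a_p[:, 1]
            w = 1.0 / (1.0 - rho**2)
            ca = w * (r_p[:, 0] - rho * np.sqrt(sa / sb) * r_p[:, 1])
            cb = w * (r_p[:, 1] - rho * np.sqrt(sb / sa) * r_p[:, 0])
            g_p = Xp[:, 0, :] * ca[:, None] + Xp[:, 1, :] * cb[:, None]
            M += g_p.T @ g_p
        B_inv = np.linalg.inv(B)
        cov = B_inv @ M @ B_inv
    except np.linalg.LinAlgError as exc:
        return _nonconverged("gee", names, f"singular working solve: {exc}")
    bse = np.sqrt(np.clip(np.diag(cov), 0, None))
    ok = converged and bool(np.isfinite(bse).all() and (bse > 0).all())
    diagnostics: dict[str, Any] = {"working_correlation": float(rho)}
    if no_pairs:
        diagnostics["note"] = "no clusters of size 2; working correlation fixed at 0"
    return FitResult(
        method="gee",
        estimates=dict(zip(names, beta)),
        standard_errors=dict(zip(names, bse)),
        variance_estimate=None,
        converged=ok,
        n_iterations=n_iter,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# divergence filter


def apply_divergence_filter(
    result: FitResult, threshold: float = DIVERGENCE_THRESHOLD
) -> FitResult:
    """Discard fits reporting any parameter strictly above ``threshold``.

    Occasionally an estimation run returns estimates of implausible
    magnitude instead of an error; such a fit is treated as non-converged
    and all its estimates and standard errors are replaced by missing
    values.  The variance component counts as a parameter, since it is
    collected alongside the coefficients.  A value exactly at the
    threshold passes.  Idempotent.
    """
    values = list(result.estimates.values())
    if result.variance_estimate is not None:
        values = values + [result.variance_estimate]
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size and np.any(np.abs(finite) > threshold):
        nan = float("nan")
        return replace(
            result,
            estimates={k: nan for k in result.estimates},
            standard_errors={k: nan for k in result.standard_errors},
            variance_estimate=None,
            converged=False,
            diagnostics={**result.diagnostics, "divergence_filtered": True},
        )
    return result
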