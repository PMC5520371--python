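"""Monte-Carlo comparison metrics for replicate fit collections.

All metrics are computed over the converged fits only, per method and per
parameter, so denominators may differ between methods.  Conditional
(cluster-specific) methods -- logistic, PQL, adaptive Gauss-Hermite -- are
judged against the generating conditional coefficients; GEE estimates a
marginal (population-average) effect and is judged against the converted
target

    beta_marginal = sqrt(1 / (0.346 * sigma2 + 1)) * beta_conditional,

the standard logit attenuation approximation for a normal random intercept
with true variance ``sigma2``.  Logistic regression is deliberately left
unconverted: in practice its coefficients are read as if they were
conditional effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .estimators import FitResult
from .synthetic_data import Scenario, ValidationError

__all__ = [
    "ATTENUATION_COEF",
    "ParamMetrics",
    "MethodSummary",
    "relative_bias",
    "convert_to_marginal",
    "empirical_bias_ci",
    "coverage_95",
    "mean_squared_error",
    "nonconvergence_rate",
    "summarize_scenario",
    "summaries_to_frame",
]

#: coefficient in the conditional-to-marginal attenuation factor
#: sqrt(1 / (c * sigma2 + 1)); c = (16*sqrt(3) / (15*pi))**2 ~= 0.346
ATTENUATION_COEF = 0.346

_Z95 = 1.96

MARGINAL_METHODS = frozenset({"gee"})
VARIANCE_METHODS = frozenset({"glmm_pql", "glmm_agq"})


def relative_bias(estimates: Sequence[float], beta_true: float) -> float:
    """Mean of (estimate - truth) / truth; positive means overestimation."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValidationError("no converged estimates")
    if beta_true == 0:
        raise ValidationError("relative bias is undefined for a zero true coefficient")
    return float(np.mean((est - beta_true) / beta_true))


def convert_to_marginal(beta_conditional: float, sigma2_true: float) -> float:
    """Attenuate a conditional logit coefficient to its marginal counterpart."""
    if sigma2_true < 0:
        raise ValidationError("variance must be non-negative")
    return float(beta_conditional * math.sqrt(1.0 / (ATTENUATION_COEF * sigma2_true + 1.0)))


def empirical_bias_ci(
    estimates: Sequence[float], beta_true: float
) -> tuple[float, float, float]:
    """Mean estimate minus truth, with a normal-approximation 95% CI."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise ValidationError("need at least two converged estimates")
    bias = float(est.mean() - beta_true)
    half = _Z95 * float(est.std(ddof=1)) / math.sqrt(est.size)
    return bias, bias - half, bias + half


def coverage_95(
    estimates: Sequence[float], ses: Sequence[float], beta_true: float
) -> float:
    """Share of Wald intervals (estimate +/- 1.96 SE) containing the truth."""
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.shape != se.shape:
        raise ValidationError("estimates and standard errors differ in length")
    if est.size == 0:
        raise ValidationError("no converged estimates")
    inside = (est - _Z95 * se <= beta_true) & (beta_true <= est + _Z95 * se)
    return float(inside.mean())


def mean_squared_error(estimates: Sequence[float], beta_true: float) -> float:
    """Sampling variance (n-1 denominator) plus squared bias."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise ValidationError("need at least two converged estimates")
    return float(est.var(ddof=1) + (est.mean() - beta_true) ** 2)


def nonconvergence_rate(results: Sequence[FitResult]) -> float:
    """Percent of replicates flagged non-converged (after the filter)."""
    if len(results) == 0:
        raise ValidationError("empty result list")
    return 100.0 * sum(not r.converged for r in results) / len(results)


@dataclass(frozen=True)
class ParamMetrics:
    beta_target: float
    relative_bias: float
    empirical_bias: float
    ci_low: float
    ci_high: float
    coverage: float
    mse: float


@dataclass(frozen=True)
class MethodSummary:
    method: str
    n_total: int
    n_converged: int
    nonconvergence_pct: float
    params: Mapping[str, ParamMetrics]
    variance_mean: float | None = None
    variance_sd: float | None = None


def _truth_for(method: str, name: str, truth: Mapping[str, float], sigma2: float) -> float:
    beta = truth[name]
    if method in MARGINAL_METHODS:
        return convert_to_marginal(beta, sigma2)
    return beta


def summarize_scenario(
    results: Mapping[str, Sequence[FitResult]],
    scenario: Scenario,
    parameters: Iterable[str] | None = None,
) -> list[MethodSummary]:
    """Per-method bias/coverage/MSE summary for one scenario.

    Metrics are computed from the converged subset; CI and MSE require at
    least two converged fits and are reported as NaN otherwise.
    """
    spec = scenario.outcome_spec
    truth = {"intercept": spec.intercept, **spec.coefficients}
    names = list(parameters) if parameters is not None else list(truth)
    sigma2 = spec.random_intercept_variance
    summaries = []
    for method, fits in results.items():
        if len(fits) == 0:
            raise ValidationError(f"no fit results for method {method!r}")
        conv = [f for f in fits if f.converged]
        per_param: dict[str, ParamMetrics] = {}
        for name in names:
            target = _truth_for(method, name, truth, sigma2)
            est = np.array([f.estimates[name] for f in conv], dtype=float)
            se = np.array([f.standard_errors[name] for f in conv], dtype=float)
            if est.size == 0:
                per_param[name] = ParamMetrics(target, *([float("nan")] * 6))
                continue
            rb = relative_bias(est, target) if target != 0 else float("nan")
            if est.size >= 2:
                bias, lo, hi = empirical_bias_ci(est, target)
                mse = mean_squared_error(est, target)
            else:
                bias = float(est.mean() - target)
                lo = hi = mse = float("nan")
            cov = coverage_95(est, se, target)
            per_param[name] = ParamMetrics(target, rb, bias, lo, hi, cov, mse)
        var_mean = var_sd = None
        if method in VARIANCE_METHODS:
            vs = np.array(
                [f.variance_estimate for f in conv if f.variance_estimate is not None],
                dtype=float,
            )
            if vs.size:
                var_mean = float(vs.mean())
                var_sd = float(vs.std(ddof=1)) if vs.size >= 2 else float("nan")
        summaries.append(
            MethodSummary(
                method=method,
                n_total=len(fits),
                n_converged=len(conv),
                nonconvergence_pct=nonconvergence_rate(fits),
                params=per_param,
                variance_mean=var_mean,
                variance_sd=var_sd,
            )
        )
    return summaries


def summaries_to_frame(
    summaries: Sequence[MethodSummary], scenario: Scenario
) -> pd.DataFrame:
    """Tidy frame: one row per (scenario, method, parameter).

    Bias columns are also exported on the x1e4 scale conventionally used
    for per-gram birthweight coefficients.
    """
    spec = scenario.outcome_spec
    rows = []
    for s in summaries:
        for name, m in s.params.items():
            rows.append(
                {
                    "scenario": scenario.label(),
                    "outcome": spec.outcome_name,
                    "n_covariates": spec.n_covariates,
                    "n_clusters": scenario.n_clusters,
                    "twin_pct": 100.0 * scenario.twin_fraction,
                    "variance": spec.random_intercept_variance,
                    "method": s.method,
                    "param": name,
                    "beta_target": m.beta_target,
                    "rel_bias": m.relative_bias,
                    "emp_bias": m.empirical_bias,
                    "ci_lo": m.ci_low,
                    "ci_hi": m.ci_high,
                    "emp_bias_e4": 1e4 * m.empirical_bias,
                    "ci_lo_e4": 1e4 * m.ci_low,
                    "ci_hi_e4": 1e4 * m.ci_high,
                    "coverage": m.coverage,
                    "mse": m.mse,
                    "nonconv_pct": s.nonconvergence_pct,
                    "var_mean": float("nan") if s.variance_mean is None else s.variance_mean,
                    "var_sd": float("nan") if s.variance_sd is None else s.variance_sd,
                    "n_converged": s.n_converged,
                }
            )
    return pd.DataFrame(rows)
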