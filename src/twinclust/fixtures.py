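"""Packaged simulation inputs: reference coefficients and covariate fixtures.

``REFERENCE_COEFFICIENTS`` holds the logit-scale regression parameters
estimated on the UKOS preterm-infant cohort (random-intercept logistic
fits) that the simulation scenarios reuse as generating truth: one set per
outcome (in-hospital death; oxygen dependence at 36 weeks post-menstrual
age) and covariate count (2 or 4).

The cohort's covariate distribution itself is not available, so the
package ships synthetic stand-in fixtures (see ``data/synthetic_ukos_*``)
with realistic extremely-preterm ranges.  Because the stand-in covariate
distribution differs from the original, the generating intercepts are
re-calibrated at run time so that simulated outcome prevalences match the
cohort's observed rates: 26% for death and 56% for oxygen dependence.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

from .synthetic_data import CovariateModel, OutcomeSpec, calibrate_intercept

__all__ = [
    "REFERENCE_COEFFICIENTS",
    "TARGET_PREVALENCE",
    "load_covariate_model",
    "outcome_spec",
    "calibrated_spec",
]

TARGET_PREVALENCE = {"death": 0.26, "o2dep": 0.56}

# (outcome, number of covariates) -> (intercept, slopes, random-intercept variance)
REFERENCE_COEFFICIENTS: dict[tuple[str, int], OutcomeSpec] = {
    ("death", 4): OutcomeSpec(
        outcome_name="death",
        intercept=10.70,
        coefficients={
            "bweight": -0.004,
            "sex": 0.410,
            "gestage": -0.039,
            "apgar": -0.212,
        },
        random_intercept_variance=0.48,
    ),
    ("death", 2): OutcomeSpec(
        outcome_name="death",
        intercept=3.037,
        coefficients={"bweight": -0.006, "sex": 0.598},
        random_intercept_variance=0.79,
    ),
    ("o2dep", 4): OutcomeSpec(
        outcome_name="o2dep",
        intercept=14.7,
        coefficients={
            "bweight": -0.0045,
            "sex": 0.954,
            "gestage": -0.058,
            "smoking": 0.654,
        },
        random_intercept_variance=2.80,
    ),
    ("o2dep", 2): OutcomeSpec(
        outcome_name="o2dep",
        intercept=5.315,
        coefficients={"bweight": -0.006, "sex": 1.001},
        random_intercept_variance=2.95,
    ),
}

_FIXTURE_FILES = {
    "death": "synthetic_ukos_death.json",
    "o2dep": "synthetic_ukos_o2dep.json",
}


@lru_cache(maxsize=None)
def load_covariate_model(outcome: str) -> CovariateModel:
    """Load the packaged synthetic covariate fixture for an outcome."""
    try:
        fname = _FIXTURE_FILES[outcome]
    except KeyError:
        raise KeyError(f"unknown outcome {outcome!r}; expected one of {sorted(_FIXTURE_FILES)}")
    text = resources.files("twinclust.data").joinpath(fname).read_text()
    return CovariateModel.from_json(json.loads(text))


def outcome_spec(outcome: str, n_covariates: int, variance: float | None = None) -> OutcomeSpec:
    """Reference outcome spec, optionally with the scenario's variance."""
    spec = REFERENCE_COEFFICIENTS[(outcome, n_covariates)]
    if variance is not None:
        spec = spec.with_(random_intercept_variance=float(variance))
    return spec


@lru_cache(maxsize=None)
def _calibrated_intercept(
    outcome: str, n_covariates: int, variance: float | None, n_mc: int, seed: int
) -> float:
    model = load_covariate_model(outcome)
    spec = outcome_spec(outcome, n_covariates, variance)
    return calibrate_intercept(
        model, spec, TARGET_PREVALENCE[outcome], n_mc=n_mc, seed=seed
    )


def calibrated_spec(
    outcome: str,
    n_covariates: int,
    variance: float | None = None,
    n_mc: int = 200_000,
    seed: int = 2017,
) -> OutcomeSpec:
    """Outcome spec with its intercept calibrated to the observed prevalence.

    Calibration is repeated per (outcome, covariate count, variance)
    because the marginal prevalence depends on the random-intercept
    variance; results are cached within the process.
    """
    spec = outcome_spec(outcome, n_covariates, variance)
    b0 = _calibrated_intercept(
        outcome, n_covariates, None if variance is None else float(variance), n_mc, seed
    )
    return spec.with_(intercept=b0)
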