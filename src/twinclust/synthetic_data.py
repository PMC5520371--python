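"""Simulation of perinatal cohorts that mix singleton births with twin pairs.

The generator emulates the structure of a preterm-infant cohort (such as
UKOS): most records are independent singletons, a small fraction are twin
pairs whose members share a birth.  Covariates are drawn from multivariate
normal distributions stratified by the combination of categorical covariate
levels (sex, maternal smoking), separately for singletons and -- jointly
over both siblings -- for twin pairs, so that siblings are positively
correlated in birthweight and essentially share gestational age.  The binary
outcome follows a two-level logistic model

    logit(p_ij) = beta_0 + u_0i + beta_1 * x_ij1 + ... + beta_k * x_ijk

where ``i`` indexes the birth (cluster), ``j`` the infant within the birth,
and ``u_0i ~ N(0, sigma2)`` is a cluster-level random intercept shared by
both twins of a pair.  Outcomes are conditionally independent Bernoulli
draws given the random intercept.
"""

from __future__ import annotations

import json
import math
import zlib
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "ValidationError",
    "ConfigurationError",
    "CalibrationError",
    "Profile",
    "CovariateModel",
    "OutcomeSpec",
    "Scenario",
    "ClusteredDataset",
    "SINGLETON",
    "TWIN_PAIR",
    "allocate_clusters",
    "draw_categorical_profiles",
    "draw_continuous_covariates",
    "apply_apgar_truncation",
    "simulate_random_intercepts",
    "outcome_probability",
    "draw_outcomes",
    "simulate_dataset",
    "calibrate_intercept",
]

SINGLETON = "singleton"
TWIN_PAIR = "twin_pair"

_PROB_TOL = 1e-12


class ValidationError(ValueError):
    """An input violates a precondition (negative count, bad probability...)."""


class ConfigurationError(ValueError):
    """A covariate model is incomplete or inconsistent."""


class CalibrationError(RuntimeError):
    """Intercept calibration could not bracket the target prevalence."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Profile:
    """One combination of categorical covariate levels.

    ``levels`` maps each categorical covariate name to the numeric code used
    in the regression (e.g. ``{"sex": 1}`` for a male infant).  Separate
    selection probabilities are kept for singleton births and twin births;
    both members of a twin pair share the profile.
    """

    levels: Mapping[str, float]
    prob_singleton: float
    prob_twin: float

    def key(self, categorical_names: Sequence[str]) -> tuple[float, ...]:
        return tuple(float(self.levels[name]) for name in categorical_names)

    def label(self, categorical_names: Sequence[str]) -> str:
        return "|".join(f"{n}={self.levels[n]:g}" for n in categorical_names)


@dataclass(frozen=True)
class CovariateModel:
    """Stratified multivariate-normal covariate distribution.

    For every (cluster kind, categorical profile) pair a mean vector and
    covariance matrix of the continuous covariates is stored.  For twin
    pairs the block is ``2k``-dimensional: the first ``k`` coordinates are
    the first sibling's covariates, the last ``k`` the second sibling's, so
    the off-diagonal ``k x k`` block carries the cross-sibling correlation.
    ``truncation`` maps a covariate name to the name of a post-processing
    rule (currently ``"apgar"``).
    """

    continuous_names: tuple[str, ...]
    categorical_names: tuple[str, ...]
    profiles: tuple[Profile, ...]
    mvn: Mapping[tuple[str, tuple[float, ...]], tuple[np.ndarray, np.ndarray]]
    truncation: Mapping[str, str] = field(default_factory=dict)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return self.continuous_names + self.categorical_names

    def profile_table(self, cluster_kind: str) -> tuple[tuple[Profile, ...], np.ndarray]:
        if cluster_kind == SINGLETON:
            probs = np.array([p.prob_singleton for p in self.profiles], dtype=float)
        elif cluster_kind == TWIN_PAIR:
            probs = np.array([p.prob_twin for p in self.profiles], dtype=float)
        else:
            raise ValidationError(f"unknown cluster kind {cluster_kind!r}")
        return self.profiles, probs

    def validate(self) -> None:
        if not self.profiles:
            raise ConfigurationError("covariate model has no categorical profiles")
        k = len(self.continuous_names)
        for kind in (SINGLETON, TWIN_PAIR):
            _, probs = self.profile_table(kind)
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"{kind} profile probabilities sum to {probs.sum()!r}, not 1"
                )
            if (probs < 0).any():
                raise ConfigurationError("negative profile probability")
        for (kind, key), (mean, cov) in self.mvn.items():
            dim = k if kind == SINGLETON else 2 * k
            if mean.shape != (dim,) or cov.shape != (dim, dim):
                raise ConfigurationError(
                    f"mvn block for {kind} profile {key} has wrong dimension "
                    f"(expected {dim}, got mean {mean.shape}, cov {cov.shape})"
                )
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ConfigurationError(f"covariance for {kind} {key} is not symmetric")
            eig = np.linalg.eigvalsh(cov)
            if eig.min() < -1e-8 * max(1.0, eig.max()):
                raise ConfigurationError(
                    f"covariance for {kind} {key} is not positive semi-definite"
                )
        for name in self.truncation:
            if name not in self.continuous_names:
                raise ConfigurationError(f"truncation rule for unknown covariate {name!r}")

    # -- JSON round trip ----------------------------------------------------

    @classmethod
    def from_json(cls, source: str | dict) -> "CovariateModel":
        data = json.loads(source) if isinstance(source, str) else source
        continuous = tuple(data["continuous"])
        categorical = tuple(data["categorical"])
        profiles = tuple(
            Profile(
                levels={n: float(v) for n, v in p["levels"].items()},
                prob_singleton=float(p["prob_singleton"]),
                prob_twin=float(p["prob_twin"]),
            )
            for p in data["profiles"]
        )
        mvn: dict[tuple[str, tuple[float, ...]], tuple[np.ndarray, np.ndarray]] = {}
        for label, blocks in data["mvn"].items():
            key = tuple(float(part.split("=")[1]) for part in label.split("|")) if label else ()
            for kind in (SINGLETON, TWIN_PAIR):
                block = blocks[kind]
                mvn[(kind, key)] = (
                    np.asarray(block["mean"], dtype=float),
                    np.asarray(block["cov"], dtype=float),
                )
        model = cls(
            continuous_names=continuous,
            categorical_names=categorical,
            profiles=profiles,
            mvn=mvn,
            truncation=dict(data.get("truncation", {})),
        )
        model.validate()
        return model

    def to_json(self) -> str:
        payload: dict[str, Any] = {
            "continuous": list(self.continuous_names),
            "categorical": list(self.categorical_names),
            "profiles": [
                {
                    "levels": dict(p.levels),
                    "prob_singleton": p.prob_singleton,
                    "prob_twin": p.prob_twin,
                }
                for p in self.profiles
            ],
            "mvn": {},
            "truncation": dict(self.truncation),
        }
        for profile in self.profiles:
            label = profile.label(self.categorical_names)
            key = profile.key(self.categorical_names)
            payload["mvn"][label] = {
                kind: {
                    "mean": self.mvn[(kind, key)][0].tolist(),
                    "cov": self.mvn[(kind, key)][1].tolist(),
                }
                for kind in (SINGLETON, TWIN_PAIR)
            }
        return json.dumps(payload, indent=1)


@dataclass(frozen=True)
class OutcomeSpec:
    """Generating parameters for one outcome: logit-scale coefficients.

    ``coefficients`` maps covariate names to slopes (per gram for
    birthweight, per week for gestational age, indicator contrasts for sex
    and smoking); ``random_intercept_variance`` is on the squared-logit
    scale.
    """

    outcome_name: str
    intercept: float
    coefficients: Mapping[str, float]
    random_intercept_variance: float

    def __post_init__(self) -> None:
        if self.random_intercept_variance < 0:
            raise ValidationError("random-intercept variance must be non-negative")

    @property
    def n_covariates(self) -> int:
        return len(self.coefficients)

    def with_(self, **changes: float) -> "OutcomeSpec":
        return replace(self, **changes)


@dataclass(frozen=True)
class Scenario:
    """One cell of the simulation grid."""

    n_clusters: int
    twin_fraction: float
    outcome_spec: OutcomeSpec
    covariate_model: CovariateModel
    n_reps: int = 1
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.twin_fraction <= 1.0:
            raise ValidationError("twin_fraction must be in [0, 1]")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be at least 1")
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be at least 1")
        extra = set(self.outcome_spec.coefficients) - set(self.covariate_model.covariate_names)
        if extra:
            raise ConfigurationError(f"coefficients for unknown covariates: {sorted(extra)}")

    @property
    def n_covariates(self) -> int:
        return self.outcome_spec.n_covariates

    def scenario_hash(self) -> int:
        spec = self.outcome_spec
        canon = json.dumps(
            [
                self.n_clusters,
                round(self.twin_fraction, 12),
                spec.outcome_name,
                sorted((k, round(v, 12)) for k, v in spec.coefficients.items()),
                round(spec.intercept, 12),
                round(spec.random_intercept_variance, 12),
            ]
        )
        return zlib.crc32(canon.encode())

    def rng(self, replicate_index: int) -> np.random.Generator:
        seq = np.random.SeedSequence(
            [int(self.master_seed) % (2**31), self.scenario_hash(), int(replicate_index)]
        )
        return np.random.default_rng(seq)

    def label(self) -> str:
        spec = self.outcome_spec
        return (
            f"{spec.outcome_name}_k{spec.n_covariates}_c{self.n_clusters}"
            f"_t{round(100 * self.twin_fraction):g}_v{spec.random_intercept_variance:g}"
        )


@dataclass
class ClusteredDataset:
    """Long-format clustered data: one row per infant.

    Columns: ``cluster_id``, ``member`` (1 or 2), ``y`` and one column per
    covariate.  ``provenance`` records how the dataset was produced.
    """

    frame: pd.DataFrame
    provenance: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        required = {"cluster_id", "member", "y"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"dataset is missing columns {sorted(missing)}")
        sizes = self.frame.groupby("cluster_id").size()
        if not sizes.isin([1, 2]).all():
            raise ValidationError("clusters must have exactly 1 or 2 members")
        dup = self.frame.duplicated(subset=["cluster_id", "member"])
        if dup.any():
            raise ValidationError("member index must be unique within cluster")
        if self.frame.isna().any().any():
            raise ValidationError("dataset contains missing values")
        if not self.frame["y"].isin([0, 1]).all():
            raise ValidationError("outcome must be binary 0/1")

    @property
    def n_clusters(self) -> int:
        return self.frame["cluster_id"].nunique()

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("cluster_id", "member", "y")]

    def to_csv(self, path_or_none=None) -> str | None:
        cols = ["cluster_id", "member", "y", *self.covariate_names]
        return self.frame[cols].to_csv(path_or_none, index=False)

    @classmethod
    def from_csv(cls, path) -> "ClusteredDataset":
        frame = pd.read_csv(path)
        ds = cls(frame=frame, provenance={"source": str(path)})
        ds.validate()
        return ds


# ---------------------------------------------------------------------------
# elementary operations


def allocate_clusters(n_clusters: int, twin_fraction: float) -> tuple[int, int]:
    """Split ``n_clusters`` birth events into singletons and twin pairs.

    The number of twin pairs is ``twin_fraction * n_clusters`` rounded half
    away from zero, so a 2% twin share of 150 clusters yields exactly 3
    pairs.
    """
    if n_clusters < 1:
        raise ValidationError("n_clusters must be at least 1")
    if not 0.0 <= twin_fraction <= 1.0:
        raise ValidationError("twin_fraction must be in [0, 1]")
    n_twin_pairs = int(math.floor(twin_fraction * n_clusters + 0.5))
    return n_clusters - n_twin_pairs, n_twin_pairs


def draw_categorical_profiles(
    n_draws: int,
    profile_table: tuple[Sequence[Profile], np.ndarray],
    rng: np.random.Generator,
) -> list[Profile]:
    """Draw cluster-level categorical profiles from a multinomial table.

    Each cluster receives one profile; both members of a twin pair share it
    (twins therefore share sex and maternal smoking status).
    """
    profiles, probs = profile_table
    if len(profiles) == 0:
        raise ValidationError("empty profile table")
    probs = np.asarray(probs, dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
        raise ValidationError("profile probabilities must be non-negative and sum to 1")
    if n_draws < 0:
        raise ValidationError("n_draws must be non-negative")
    if n_draws == 0:
        return []
    idx = rng.choice(len(profiles), size=n_draws, p=probs / probs.sum())
    return [profiles[i] for i in idx]


def apply_apgar_truncation(value):
    """Fold overshooting continuous Apgar scores back into the 0-10 range.

    Generated values above 12 are replaced by 10 and values in (10, 12] by
    9; anything at or below 10 passes through.  The rule is idempotent and
    keeps the score continuous.
    """
    arr = np.asarray(value, dtype=float)
    out = np.where(arr > 12, 10.0, np.where(arr > 10, 9.0, arr))
    if np.isscalar(value) or arr.ndim == 0:
        return float(out)
    return out


TRUNCATION_RULES = {"apgar": apply_apgar_truncation}


def _apply_truncation(model: CovariateModel, name: str, values):
    rule = model.truncation.get(name)
    if rule is None:
        return values
    try:
        func = TRUNCATION_RULES[rule]
    except KeyError:
        raise ConfigurationError(f"unknown truncation rule {rule!r} for {name!r}") from None
    return func(values)


def draw_continuous_covariates(
    profile: Profile,
    cluster_kind: str,
    model: CovariateModel,
    rng: np.random.Generator,
    size: int = 1,
):
    """Draw continuous covariates for ``size`` clusters of one profile.

    Singletons yield an array of shape ``(size, k)``; twin pairs an array of
    shape ``(size, 2, k)`` drawn jointly from the ``2k``-dimensional normal
    so cross-sibling correlations are preserved.  Truncation rules are
    applied afterwards.
    """
    key = profile.key(model.categorical_names)
    try:
        mean, cov = model.mvn[(cluster_kind, key)]
    except KeyError:
        raise ConfigurationError(
            f"no multivariate-normal parameters for {cluster_kind} profile "
            f"{profile.label(model.categorical_names)!r}"
        ) from None
    k = len(model.continuous_names)
    draws = rng.multivariate_normal(mean, cov, size=size)
    if cluster_kind == TWIN_PAIR:
        draws = draws.reshape(size, 2, k)
    for j, name in enumerate(model.continuous_names):
        draws[..., j] = _apply_truncation(model, name, draws[..., j])
    return draws


def simulate_random_intercepts(
    n_clusters: int, sigma2: float, rng: np.random.Generator
) -> np.ndarray:
    """Independent N(0, sigma2) birth-level effects, one per cluster."""
    if sigma2 < 0:
        raise ValidationError("variance must be non-negative")
    return rng.normal(0.0, math.sqrt(sigma2), size=n_clusters)


def outcome_probability(covariates, u0, spec: OutcomeSpec):
    """Inverse-logit of the two-level linear predictor.

    ``covariates`` may be a mapping of scalars or a DataFrame of columns;
    ``u0`` is the cluster effect (scalar or aligned vector).  Numerically
    stable for linear predictors of any magnitude.
    """
    eta = spec.intercept + np.asarray(u0, dtype=float)
    for name, beta in spec.coefficients.items():
        try:
            x = covariates[name]
        except KeyError:
            raise ValidationError(f"covariate {name!r} missing from data") from None
        eta = eta + beta * np.asarray(x, dtype=float)
    return expit(eta)


def draw_outcomes(probabilities, rng: np.random.Generator) -> np.ndarray:
    """Conditionally independent Bernoulli outcomes given cluster effects."""
    p = np.asarray(probabilities, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("probabilities must lie in [0, 1]")
    return rng.binomial(1, p)


# ---------------------------------------------------------------------------
# dataset assembly


def _draw_covariate_frame(
    model: CovariateModel,
    n_singletons: int,
    n_twin_pairs: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Covariate rows for ``n_singletons`` + ``n_twin_pairs`` clusters.

    Clusters are numbered 1..n with singletons first.  Random draws happen
    in a fixed order (singleton profiles, twin profiles, then continuous
    blocks per kind and per profile in model order) so output is fully
    reproducible from the generator state.
    """
    prof_s = draw_categorical_profiles(n_singletons, model.profile_table(SINGLETON), rng)
    prof_t = draw_categorical_profiles(n_twin_pairs, model.profile_table(TWIN_PAIR), rng)
    k = len(model.continuous_names)

    cont_s = np.empty((n_singletons, k))
    cont_t = np.empty((n_twin_pairs, 2, k))
    for kind, prof_list, target in ((SINGLETON, prof_s, cont_s), (TWIN_PAIR, prof_t, cont_t)):
        assignment = np.array([model.profiles.index(p) for p in prof_list], dtype=int)
        for i, profile in enumerate(model.profiles):
            rows = np.flatnonzero(assignment == i)
            if rows.size == 0:
                continue
            target[rows] = draw_continuous_covariates(profile, kind, model, rng, size=rows.size)

    records: dict[str, np.ndarray] = {}
    n_rows = n_singletons + 2 * n_twin_pairs
    cluster_id = np.concatenate(
        [
            np.arange(1, n_singletons + 1),
            np.repeat(np.arange(n_singletons + 1, n_singletons + n_twin_pairs + 1), 2),
        ]
    ).astype(int)
    member = np.concatenate(
        [np.ones(n_singletons, dtype=int), np.tile([1, 2], n_twin_pairs)]
    )
    records["cluster_id"] = cluster_id
    records["member"] = member
    for j, name in enumerate(model.continuous_names):
        records[name] = np.concatenate([cont_s[:, j], cont_t[:, :, j].reshape(-1)])
    for name in model.categorical_names:
        vals_s = np.array([p.levels[name] for p in prof_s], dtype=float)
        vals_t = np.repeat(np.array([p.levels[name] for p in prof_t], dtype=float), 2)
        records[name] = np.concatenate([vals_s, vals_t])
    frame = pd.DataFrame(records)
    assert len(frame) == n_rows
    return frame


def simulate_dataset(scenario: Scenario, replicate_index: int) -> ClusteredDataset:
    """Generate one replicate dataset for a scenario.

    Composes cluster allocation, stratified covariate draws, random
    intercepts and Bernoulli outcomes.  Deterministic given
    ``(master_seed, scenario, replicate_index)``.
    """
    rng = scenario.rng(replicate_index)
    n_s, n_t = allocate_clusters(scenario.n_clusters, scenario.twin_fraction)
    frame = _draw_covariate_frame(scenario.covariate_model, n_s, n_t, rng)
    u0 = simulate_random_intercepts(
        scenario.n_clusters, scenario.outcome_spec.random_intercept_variance, rng
    )
    u0_rows = u0[frame["cluster_id"].to_numpy() - 1]
    p = outcome_probability(frame, u0_rows, scenario.outcome_spec)
    frame = frame.copy()
    frame.insert(2, "y", draw_outcomes(p, rng))
    ds = ClusteredDataset(
        frame=frame,
        provenance={
            "scenario": scenario.label(),
            "replicate": int(replicate_index),
            "master_seed": int(scenario.master_seed),
        },
    )
    return ds


def calibrate_intercept(
    model: CovariateModel,
    spec: OutcomeSpec,
    target_prevalence: float,
    n_mc: int = 200_000,
    seed: int = 2017,
    twin_fraction: float = 0.1,
) -> float:
    """Adjust the intercept so the simulated marginal prevalence hits a target.

    A single Monte-Carlo panel of ``n_mc`` infants (covariates plus random
    intercepts at the spec's variance) is drawn once; the expected
    prevalence ``mean(expit(b0 + eta_rest))`` is then a smooth, strictly
    increasing function of the intercept and the target is solved for by
    root bracketing.  All slope coefficients are left untouched.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValidationError("target prevalence must be in (0, 1)")
    if n_mc < 10_000:
        raise ValidationError("n_mc must be at least 10,000 for a stable calibration")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 929_203_771]))
    n_clusters = max(1, int(round(n_mc / (1.0 + twin_fraction))))
    n_s, n_t = allocate_clusters(n_clusters, twin_fraction)
    frame = _draw_covariate_frame(model, n_s, n_t, rng)
    u0 = simulate_random_intercepts(n_clusters, spec.random_intercept_variance, rng)
    base = u0[frame["cluster_id"].to_numpy() - 1].astype(float)
    for name, beta in spec.coefficients.items():
        if name not in frame:
            raise ValidationError(f"covariate {name!r} missing from covariate model")
        base = base + beta * frame[name].to_numpy(dtype=float)

    def gap(b0: float) -> float:
        return float(np.mean(expit(b0 + base))) - target_prevalence

    lo, hi = spec.intercept - 40.0, spec.intercept + 40.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise CalibrationError(
            f"prevalence target {target_prevalence} not bracketed in [{lo}, {hi}]"
        )
    return float(brentq(gap, lo, hi, xtol=1e-10))
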