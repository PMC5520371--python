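"""Scenario-grid orchestration: simulate, fit, summarise, render.

Runs the full Monte-Carlo design -- number of clusters x percentage of twin
pairs x random-intercept variance x outcome x covariate count -- with
per-replicate seed substreams, so results are reproducible regardless of
how many worker processes execute the replicates.  Within a replicate the
same simulated dataset is analysed by every requested method.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import estimators, evaluation, fixtures
from .synthetic_data import (
    ClusteredDataset,
    ConfigurationError,
    Scenario,
    ValidationError,
    simulate_dataset,
)

__all__ = [
    "GridSpec",
    "METHOD_REGISTRY",
    "run_replicate",
    "run_scenario",
    "run_grid",
    "render_tables",
    "scenario_from_config",
]

logger = logging.getLogger("twinclust")

METHOD_REGISTRY = {
    "logistic": estimators.fit_logistic,
    "pql": estimators.fit_glmm_pql,
    "agq": estimators.fit_glmm_agq,
    "gee": estimators.fit_gee_exchangeable,
}

# registry key -> FitResult.method name
_METHOD_NAMES = {"logistic": "logistic", "pql": "glmm_pql", "agq": "glmm_agq", "gee": "gee"}


@dataclass(frozen=True)
class GridSpec:
    """The scenario grid of the simulation design."""

    n_clusters_list: tuple[int, ...] = (150, 500, 1000)
    twin_pct_list: tuple[float, ...] = (2.0, 5.0, 10.0, 20.0)
    variance_list: tuple[float, ...] = (0.5, 1.0, 2.0)
    outcomes: tuple[str, ...] = ("death", "o2dep")
    covariate_counts: tuple[int, ...] = (2, 4)
    n_reps: int = 5000
    master_seed: int = 20170720

    def __post_init__(self):
        for name in ("n_clusters_list", "twin_pct_list", "variance_list", "outcomes",
                     "covariate_counts"):
            if not getattr(self, name):
                raise ValidationError(f"{name} must be non-empty")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be at least 1")

    def scenarios(self) -> Iterable[Scenario]:
        for outcome in self.outcomes:
            model = fixtures.load_covariate_model(outcome)
            for k in self.covariate_counts:
                for variance in self.variance_list:
                    spec = fixtures.calibrated_spec(outcome, k, variance)
                    for n_clusters in self.n_clusters_list:
                        for pct in self.twin_pct_list:
                            yield Scenario(
                                n_clusters=n_clusters,
                                twin_fraction=pct / 100.0,
                                outcome_spec=spec,
                                covariate_model=model,
                                n_reps=self.n_reps,
                                master_seed=self.master_seed,
                            )


def _checked_fit(method_key: str, dataset: ClusteredDataset, covariates):
    fitter = METHOD_REGISTRY[method_key]
    names = ["intercept", *covariates]
    try:
        result = fitter(dataset, covariates)
    except Exception as exc:  # per-replicate failures never abort a scenario
        result = estimators._nonconverged(_METHOD_NAMES[method_key], names, f"{exc}")
    return estimators.apply_divergence_filter(result)


def run_replicate(
    scenario: Scenario, replicate_index: int, methods: Sequence[str]
) -> dict[str, estimators.FitResult]:
    """Simulate one dataset and fit every requested method to it."""
    dataset = simulate_dataset(scenario, replicate_index)
    covariates = list(scenario.outcome_spec.coefficients)
    return {m: _checked_fit(m, dataset, covariates) for m in methods}


def run_scenario(
    scenario: Scenario,
    methods: Sequence[str] = ("logistic", "pql", "agq", "gee"),
    workers: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run all replicates of one scenario.

    Returns ``(raw, summary)``: the raw frame holds one row per
    (replicate, method, parameter) with estimate and standard error plus
    the per-fit variance estimate and convergence flag; the summary frame
    is the output of :func:`evaluation.summarize_scenario`.  Replicates use
    independent seed substreams, so the result does not depend on
    ``workers``.
    """
    unknown = set(methods) - set(METHOD_REGISTRY)
    if unknown:
        raise ConfigurationError(f"unknown methods {sorted(unknown)}")
    reps = range(scenario.n_reps)
    if workers > 1:
        from joblib import Parallel, delayed

        per_rep = Parallel(n_jobs=workers)(
            delayed(run_replicate)(scenario, r, methods) for r in reps
        )
    else:
        per_rep = [run_replicate(scenario, r, methods) for r in reps]

    by_method = {
        _METHOD_NAMES[m]: [per_rep[r][m] for r in reps] for m in methods
    }
    summaries = evaluation.summarize_scenario(by_method, scenario)
    summary = evaluation.summaries_to_frame(summaries, scenario)

    rows = []
    covariates = ["intercept", *scenario.outcome_spec.coefficients]
    for r in reps:
        for m in methods:
            fit = per_rep[r][m]
            for name in covariates:
                rows.append(
                    {
                        "scenario": scenario.label(),
                        "replicate": r,
                        "method": fit.method,
                        "param": name,
                        "estimate": fit.estimates[name],
                        "se": fit.standard_errors[name],
                        "variance_estimate": fit.variance_estimate,
                        "converged": fit.converged,
                    }
                )
    return pd.DataFrame(rows), summary


def _read_manifest(path: Path) -> dict:
    if not path.exists():
        return {"completed": []}
    try:
        manifest = json.loads(path.read_text())
        assert isinstance(manifest.get("completed"), list)
        return manifest
    except (json.JSONDecodeError, AssertionError) as exc:
        raise RuntimeError(
            f"corrupt manifest at {path}; delete it to re-run the grid"
        ) from exc


def run_grid(
    grid: GridSpec,
    methods: Sequence[str] = ("logistic", "pql", "agq", "gee"),
    out_dir: str | Path | None = None,
    workers: int = 1,
    keep_raw: bool = True,
) -> pd.DataFrame:
    """Run every scenario of the grid; resumable via an on-disk manifest.

    With ``out_dir`` set, each completed scenario writes
    ``summary_<label>.csv`` (and ``raw_<label>.csv.gz`` when ``keep_raw``)
    and is recorded in ``manifest.json``; scenarios already listed there
    are skipped on re-run.  Returns the concatenated summary frame.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    manifest: dict = {"completed": []}
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        manifest = _read_manifest(out_path / "manifest.json")
    all_summaries = []
    for scenario in grid.scenarios():
        label = scenario.label()
        summary_file = out_path / f"summary_{label}.csv" if out_path else None
        if out_path is not None and label in manifest["completed"] and summary_file.exists():
            logger.info("skipping completed scenario %s", label)
            all_summaries.append(pd.read_csv(summary_file))
            continue
        logger.info("running scenario %s (%d reps)", label, scenario.n_reps)
        try:
            raw, summary = run_scenario(scenario, methods, workers=workers)
        except (ValidationError, ConfigurationError) as exc:
            raise type(exc)(f"scenario {label}: {exc}") from exc
        all_summaries.append(summary)
        if out_path is not None:
            summary.to_csv(summary_file, index=False)
            if keep_raw:
                raw.to_csv(out_path / f"raw_{label}.csv.gz", index=False)
            manifest["completed"].append(label)
            (out_path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    combined = pd.concat(all_summaries, ignore_index=True)
    if out_path is not None:
        combined.to_csv(out_path / "summaries.csv", index=False)
    return combined


_STYLES = ("bias", "coverage", "mse", "nonconvergence", "variance")


def render_tables(
    summaries: pd.DataFrame,
    style: str,
    parameter: str = "bweight",
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Arrange scenario summaries into a publication-style wide table.

    ``bias`` shows the empirical bias on the x1e-4 scale with its 95% CI;
    ``coverage``, ``mse`` and ``nonconvergence`` show those metrics by
    (twin %, variance) rows and method columns; ``variance`` shows
    "mean (sd)" of the random-intercept variance estimates.  Missing cells
    are left blank and logged.
    """
    if style not in _STYLES:
        raise ValidationError(f"unknown table style {style!r}; expected one of {_STYLES}")
    frame = summaries
    if style != "variance":
        frame = frame[frame["param"] == parameter] if len(frame) else frame
    index_cols = ["outcome", "n_covariates", "n_clusters", "twin_pct", "variance"]
    if len(frame) == 0:
        table = pd.DataFrame(columns=index_cols)
    elif style == "bias":
        body = frame.assign(
            cell=lambda d: d.apply(
                lambda r: f"{r.emp_bias_e4:.2f} [{r.ci_lo_e4:.2f} ; {r.ci_hi_e4:.2f}]",
                axis=1,
            )
        )
        table = body.pivot_table(
            index=index_cols, columns="method", values="cell", aggfunc="first"
        ).reset_index()
    elif style == "variance":
        body = frame.drop_duplicates(subset=index_cols + ["method"])
        body = body[body["var_mean"].notna()].assign(
            cell=lambda d: d.apply(lambda r: f"{r.var_mean:.2f} ({r.var_sd:.2f})", axis=1)
        )
        table = body.pivot_table(
            index=index_cols, columns="method", values="cell", aggfunc="first"
        ).reset_index()
    else:
        value = {"coverage": "coverage", "mse": "mse", "nonconvergence": "nonconv_pct"}[style]
        table = frame.pivot_table(
            index=index_cols, columns="method", values=value, aggfunc="first"
        ).reset_index()
    if table.isna().any().any():
        logger.warning("table style %s has missing scenario cells", style)
    if out_path is not None:
        out_path = Path(out_path)
        table.to_csv(out_path, index=False)
        out_path.with_suffix(".txt").write_text(table.to_string(index=False) + "\n")
    return table


def scenario_from_config(config: Mapping, n_mc_calibration: int = 200_000) -> Scenario:
    """Build a scenario from the JSON configuration mapping.

    Expected keys: ``n_clusters``, ``twin_pct`` (percent), ``variance``,
    ``outcome`` (death|o2dep), ``n_covariates`` (2|4), ``n_reps``, ``seed``.
    """
    try:
        outcome = config["outcome"]
        k = int(config["n_covariates"])
        spec = fixtures.calibrated_spec(
            outcome, k, float(config["variance"]), n_mc=n_mc_calibration
        )
        return Scenario(
            n_clusters=int(config["n_clusters"]),
            twin_fraction=float(config["twin_pct"]) / 100.0,
            outcome_spec=spec,
            covariate_model=fixtures.load_covariate_model(outcome),
            n_reps=int(config.get("n_reps", 1)),
            master_seed=int(config.get("seed", 0)),
        )
    except KeyError as exc:
        raise ConfigurationError(f"scenario config missing key {exc}") from exc
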