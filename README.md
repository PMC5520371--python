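# twinclust

Estimator reliability for binary outcomes in cohorts with a small number
of twin pairs.

Datasets of preterm infants are mostly independent singleton births with
a limited admixture of twin pairs (often 2–20% of birth events). The
twins' outcomes — such as in-hospital death or oxygen dependence at 36
weeks post-menstrual age — are correlated within a pair, and an analysis
that ignores this under-states uncertainty; but with so few and such
small clusters it is unclear whether mixed models can estimate the
dependence at all. `twinclust` is a Monte-Carlo laboratory for this
question, aimed at biostatisticians and perinatal epidemiologists: it
simulates cohorts with the structure of the UKOS preterm-infant study and
compares four analyses of the binary outcome

```
logit(p_ij) = β0 + u_0i + β1·BW_ij + β2·SEX_ij + … ,   u_0i ~ N(0, σ²)
```

where *i* indexes the birth (cluster of size 1 or 2) and *j* the infant:

1. **logistic regression** (ignores clustering; conditional β, model SEs),
2. **random-intercept logistic by PQL** (penalised quasi-likelihood with
   a REML variance update on the working model),
3. **random-intercept logistic by adaptive Gauss–Hermite quadrature**
   (exact marginal ML, 5 nodes per cluster integral, mode-recentred),
4. **GEE** with exchangeable working correlation and sandwich SEs
   (marginal β; judged against the converted target
   `β_GEE = sqrt(1/(0.346·σ² + 1))·β`).

Per scenario (clusters × twin% × σ² × outcome × number of covariates) the
package reports relative and empirical bias with 95% CIs, coverage of the
Wald 95% interval, mean squared error, non-convergence rates (including a
divergence filter that discards fits reporting any parameter above 1000
in absolute value), and the distribution of the estimated random-intercept
variance. See `docs/methods.md` for the full model and design notes.

## Worked example

Simulate one scenario — death outcome, 4 covariates, 150 birth events of
which 10% are twin pairs, random-intercept variance 1 — and compare three
methods over 200 replicates:

```python
import twinclust as tc

spec = tc.calibrated_spec("death", 4, variance=1.0)
model = tc.load_covariate_model("death")
scenario = tc.Scenario(
    n_clusters=150, twin_fraction=0.10, outcome_spec=spec,
    covariate_model=model, n_reps=200, master_seed=20170720,
)
raw, summary = tc.run_scenario(scenario, methods=("logistic", "agq", "gee"))
cols = ["method", "rel_bias", "emp_bias_e4", "coverage", "mse", "nonconv_pct"]
print(summary[summary["param"] == "bweight"][cols]
      .to_string(index=False, float_format=lambda v: f"{v:.4g}"))
```

prints

```
  method  rel_bias  emp_bias_e4  coverage       mse  nonconv_pct
logistic  -0.07254        2.902      0.95 2.212e-06            0
glmm_agq    0.1713        -6.85    0.9895  4.92e-06            5
     gee   0.06135       -2.115    0.9574 2.548e-06            6
```

Reading the birthweight row: logistic regression attenuates the
coefficient toward zero by ~7% (relative bias −0.073; the empirical bias
is printed on the ×10⁻⁴ scale, so +2.9 means the estimate is on average
2.9·10⁻⁴ logit/g above the true −0.004); the adaptive Gauss–Hermite
mixed model over-covers slightly (99%) and 5% of its fits are flagged
non-convergent at this small sample size; GEE, measured against its
converted marginal target, has the smallest relative bias here and an
MSE on par with logistic regression. `tc.render_tables`
arranges multi-scenario summaries into the bias / coverage / MSE /
variance table layouts, and `tc.run_grid` sweeps the full design with a
resumable manifest.

The same machinery is scriptable from the shell:

```bash
twinclust simulate --outcome death --n-covariates 4 --clusters 150 \
    --twin-pct 10 --seed 1 --out cohort.csv
twinclust fit --method agq --data cohort.csv \
    --covariates bweight,sex,gestage,apgar --out fit.json
twinclust grid --config grid.json --methods logistic,agq,gee \
    --reps 500 --seed 20170720 --out results/
twinclust render --summaries results/summaries.csv --style bias --out bias.csv
```

## Package layout

| module | contents |
|---|---|
| `twinclust.synthetic_data` | cluster allocation, stratified MVN covariates, Apgar folding, random intercepts, outcome simulation, intercept calibration |
| `twinclust.fixtures` | reference coefficient sets, packaged synthetic covariate fixtures, calibrated specs |
| `twinclust.estimators` | the four fitters, quadrature rule, divergence filter |
| `twinclust.evaluation` | bias / coverage / MSE / non-convergence metrics and scenario summaries |
| `twinclust.study_runner` | scenario grid, seed substreams, manifest-based resume, table rendering |
| `twinclust.cli` | `twinclust simulate|fit|evaluate|grid|render` |
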