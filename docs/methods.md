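# Methods

## The problem

Perinatal datasets are mostly independent singleton births with a small
admixture of twin pairs, whose outcomes are correlated. `twinclust`
implements a Monte-Carlo study of how four standard analyses of a binary
outcome behave in exactly this regime: ordinary logistic regression (which
ignores the clustering), the logistic random-intercept model estimated by
penalised quasi-likelihood (PQL) and by adaptive Gauss–Hermite quadrature
(AGQ), and generalised estimating equations (GEE) with an exchangeable
working correlation.

## Data-generating model

Each replicate dataset has `n_clusters` birth events; a fraction
`twin_fraction` of them (rounded half away from zero) are twin pairs, the
rest singletons. For infant *j* of birth *i*,

```
logit(p_ij) = β0 + u_0i + β1 x_ij1 + … + βk x_ijk,     u_0i ~ N(0, σ²)
```

with outcomes conditionally independent Bernoulli(p_ij) given u_0i. The
random intercept is shared by both twins of a pair and induces the
within-pair outcome correlation.

Covariates mimic an extremely-preterm cohort (the UKOS structure: 797
infants, outcomes in-hospital death 26% and oxygen dependence at 36 weeks
56%). Categorical covariates (sex; maternal smoking for the oxygen
outcome) are drawn per *cluster* from a multinomial table — twins share
them. Continuous covariates (birthweight in grams, gestational age in
weeks, a continuous Apgar score) are drawn from a multivariate normal per
(cluster kind, categorical profile); for twin pairs the joint
2k-dimensional block carries cross-sibling correlations. Simulated Apgar
values above 12 are replaced by 10 and values in (10, 12] by 9, which
folds the normal tail back into the 0–10 score range; the boundary
convention (≤ 10 unchanged, half-open intervals above) makes the rule a
total, idempotent function.

### Generating coefficients

The regression coefficients and random-intercept variances are reference
estimates from random-intercept fits to the UKOS cohort, one set per
outcome and covariate count:

| outcome | k | intercept | bweight (g) | sex (male) | gest. age (w) | Apgar / smoking | σ² |
|---|---|---|---|---|---|---|---|
| death  | 4 | 10.70 | −0.004  | 0.410 | −0.039 | −0.212 (Apgar) | 0.48 |
| death  | 2 | 3.037 | −0.006  | 0.598 | — | — | 0.79 |
| O₂ dep | 4 | 14.7  | −0.0045 | 0.954 | −0.058 | 0.654 (smoking) | 2.80 |
| O₂ dep | 2 | 5.315 | −0.006  | 1.001 | — | — | 2.95 |

Scenario grids override σ² (defaults 0.5, 1, 2).

### The synthetic covariate fixture and intercept calibration

The cohort's actual covariate distribution parameters are not available,
so the package ships *synthetic stand-ins*
(`data/synthetic_ukos_death.json`, `data/synthetic_ukos_o2dep.json`) with
ranges a neonatologist would recognise: birthweight ≈ 810–870 g (SD
160 g), gestational age ≈ 26.4 w (SD 1.4 w), Apgar ≈ 7 (SD 2), 55% male,
28% maternal smoking; twins ≈ 50 g lighter. Within an infant, birthweight
and gestational age correlate at 0.55; across siblings, birthweight
correlates at 0.70, gestational age at 0.95 and Apgar at 0.30. The
gestational-age cross-sibling value is 0.95 rather than something closer
to 1 because the joint twin covariance must stay positive definite given
the 0.55 within-infant correlation; 0.95 is the largest round value that
does.

Because the stand-in distribution differs from the original, the
generating intercept is re-calibrated at run time: a Monte-Carlo panel of
200,000 infants (covariates plus random intercepts at the scenario's σ²)
is drawn once, and the intercept solving
`mean(expit(β0 + η_rest)) = target` is found by root bracketing
(`brentq`), with targets 26% (death) and 56% (O₂ dependence). The
calibrated intercept is also the truth used when evaluating intercept
bias, since it is the parameter actually generating the data. Calibration
is repeated per scenario variance so prevalence stays at the cohort rate
across the grid; the residual error is the Monte-Carlo noise of the
panel, well under half a percentage point.

Features of real data the generator does *not* emulate: discrete Apgar
scores (kept continuous apart from the folding rule), covariate-dependent
twinning, higher-order multiples, hospital-level clustering, and any
outcome-dependent censoring. Passing tests therefore validate estimator
behaviour under the stated model, not the full messiness of cohort data.

## Estimators

All four fitters accept a long-format dataset plus covariate names and
return coefficients, standard errors, an optional variance component, a
convergence flag and diagnostics. Cluster sizes above 2 raise — the
sampling design never produces them.

* **Logistic regression** — statsmodels `Logit` (Newton IRLS);
  model-based SEs from the observed information. Clustering is ignored;
  coefficients are conditional in interpretation.
* **PQL** — iterative working-variate scheme: working response
  `z = η + (y − p)/(p(1−p))` with weights `w = p(1−p)`, a weighted
  linear-mixed-model solve for the fixed effects and cluster BLUPs
  (closed-form 1×1 / 2×2 cluster blocks), and a REML update of σ² on the
  working model by bounded 1-D minimisation, iterated until the largest
  parameter change is below 1e-6 (cap 50 outer iterations). With σ² fixed
  at 0 the scheme is plain IRLS and reproduces the logistic MLE.
* **AGQ** — exact marginal likelihood, each cluster's integral over the
  random intercept evaluated by Gauss–Hermite quadrature recentred at the
  cluster's posterior mode (vectorised Newton inner loop) and rescaled by
  the curvature there; 5 nodes by default, matching the study arm; 1 node
  gives the Laplace approximation. The outer optimisation is L-BFGS-B
  over (β, log σ) with log σ bounded in [−10, 5]; a fit pinned at the
  lower bound is reported as σ̂² = 0 with a boundary diagnostic, not as a
  failure. The design is standardised internally for conditioning
  (birthweight is in grams). An analytic score computed in the same node
  sweep (holding the adaptive centring fixed) drives the optimiser; if
  the line search aborts on the ~1e-3 centring approximation near the
  optimum, a finite-difference polish pass finishes the job. SEs come
  from a numerically differentiated observed information; the σ² SE uses
  the delta method from the log-σ scale. The 5-node rule carries an
  intrinsic ~1e-4 relative truncation error on small-cluster
  log-likelihoods; tests verify the machinery against brute-force
  integration at 25 nodes (error < 1e-6) and assert the node-count
  convergence ladder.
* **GEE** — estimating equations with logit link and binomial variance,
  solved by vectorised Fisher scoring with closed-form 1×1 / 2×2
  working-covariance blocks. The exchangeable working correlation is
  re-estimated each iteration by moments from within-pair standardised
  residual cross-products (singletons contribute nothing); the
  number-of-parameters degrees-of-freedom correction in its denominator
  is applied only when there are more pairs than parameters — with, say,
  3 pairs and 5 parameters the corrected denominator would be negative
  and silently flip the correlation's sign, so the uncorrected pair
  count is used instead. ρ̂ is clipped just below 1 for stability and a
  dataset with no pairs at all fixes ρ = 0 with a diagnostic. SEs are
  robust sandwich estimates with no small-sample correction;
  coefficients are marginal (population-average). The implementation is
  cross-checked in the test suite against statsmodels GEE (agreement to
  ~1e-13 on pairs-rich data, where the conventions coincide) and, on
  singleton-only data, against logistic regression with
  heteroscedasticity-robust (HC0) standard errors.

Cross-validation: the AGQ fitter was checked against lme4's
`glmer(..., nAGQ = 5)` on identical simulated datasets — boundary fits
agree to four decimals in log-likelihood, and on flat-likelihood
replicates (three twin pairs) both implementations agree within 0.06
log-likelihood units while lme4 emits convergence warnings.

### Non-convergence bookkeeping

A fit is recorded as non-converged when the routine errors, the optimiser
fails, or SEs are not finite and positive. In addition, the **divergence
filter** discards any fit reporting a parameter above 1000 in absolute
value — occasionally PQL, GEE or a flat-likelihood AGQ run returns
estimates of implausible magnitude instead of an error. The variance
component counts as a parameter for this rule, since it is collected
alongside the coefficients. The threshold is deliberately crude:
estimates are either moderate or enormous, so its exact value is
immaterial. All summary metrics are computed over the converged subset
per method, so denominators can differ between methods.

## Evaluation metrics

Per scenario, method and parameter: relative bias `mean((β̂ − β)/β)`;
empirical bias `mean(β̂) − β` with a normal-approximation 95% CI
(±1.96·sd/√n — the standard choice for Monte-Carlo means of thousands of
replicates); coverage of the Wald interval `β̂ ± 1.96·SE`; and
`MSE = var(β̂) + bias²` with the n−1 variance convention. Logistic, PQL
and AGQ are judged against the generating conditional coefficients;
logistic deliberately so, because practitioners read its output as if it
were conditional. GEE estimates a marginal effect and is judged against

```
β_marginal = sqrt(1 / (0.346·σ² + 1)) · β_conditional ,
```

the standard logit attenuation approximation (0.346 ≈ (16√3/15π)²). This
conversion is itself approximate: at σ² = 2 the measured attenuation of
the marginal slope under the packaged fixture is ≈ 0.80 versus the
formula's 0.769, a ~4% discrepancy that shows up as an apparent GEE
"bias" of order 1e-4 on the birthweight scale even though GEE is
consistent for the true marginal slope.

## Study runner and reproducibility

The grid (clusters × twin% × σ² × outcome × covariate count, default
5000 replicates per cell) is orchestrated with per-replicate seed
substreams: each replicate's generator is seeded from
`(master_seed, scenario hash, replicate index)` through NumPy's
`SeedSequence`, so results are byte-identical regardless of worker count
and the same simulated dataset is analysed by every method within a
replicate. Completed scenarios are recorded in an on-disk manifest and
skipped on resume. Tables are rendered in the study's layouts: empirical
bias ×1e4 with CIs, coverage, MSE, non-convergence %, and variance
"mean (SD)".

Problem sizes used by the shipped checks are reduced but faithful: the
pattern-reproduction suite runs 500 replicates of 150-cluster scenarios,
parameter recovery uses 100 replicates of 2,000 twin pairs, and the
acceptance script runs the full 5000 replicates for the GEE bias cell and
200,000 infants for each prevalence target.

## Known limitations

* The covariate fixture is a constructed stand-in; quantities that
  depend on fine details of the covariate distribution (exact bias
  magnitudes, non-convergence percentages) will differ from any specific
  cohort. Two documented consequences: with the fixture's strong
  birthweight effect, σ² is partially identified even from singletons,
  so AGQ does not collapse onto logistic at 2% twins the way it does
  when the variance is unidentifiable there; and because logistic bias
  is small at low σ² under this fixture, GEE's MSE advantage over
  logistic regression is clear only in high-variance scenarios, with
  ties inside Monte-Carlo noise elsewhere.
* PQL is implemented in its classical form and inherits its well-known
  downward bias in binary-data variance components; exact replication of
  any particular R routine's non-convergence rates is out of scope.
* Supported cluster sizes are 1 and 2 only; MCMC estimation and
  survival analysis of the death outcome are out of scope.
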