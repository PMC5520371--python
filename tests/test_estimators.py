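"""Unit tests for the four fitters and the divergence filter."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.integrate import simpson

import twinclust as tc
from twinclust.estimators import FitResult

from conftest import make_scenario, singleton_dataset, twin_pairs_dataset

NAMES4 = ["intercept", "bweight", "sex", "gestage", "apgar"]


def two_by_two_dataset():
    """10/20 events at x=0, 15/20 at x=1, all singletons."""
    rows, cid = [], 0
    for x, events, n in [(0, 10, 20), (1, 15, 20)]:
        for i in range(n):
            cid += 1
            rows.append({"cluster_id": cid, "member": 1, "y": int(i < events), "x": x})
    return tc.ClusteredDataset(pd.DataFrame(rows))


def brute_force_loglik(dataset, params, sigma2, n_grid=10_001):
    """Independent oracle: per-cluster Simpson integration over the intercept."""
    sigma = math.sqrt(sigma2)
    total = 0.0
    for _, grp in dataset.frame.groupby("cluster_id"):
        u = np.linspace(-10 * sigma, 10 * sigma, n_grid)
        eta = params["intercept"] + u[None, :]
        for name, beta in params.items():
            if name != "intercept":
                eta = eta + beta * grp[name].to_numpy()[:, None]
        y = grp["y"].to_numpy()[:, None]
        ll_y = (y * eta - np.logaddexp(0.0, eta)).sum(axis=0)
        f = np.exp(ll_y - 0.5 * u**2 / sigma2) / math.sqrt(2 * math.pi * sigma2)
        total += math.log(simpson(f, x=u))
    return total


class TestLogistic:
    def test_two_by_two_closed_form(self):
        res = tc.fit_logistic(two_by_two_dataset(), ["x"])
        assert res.converged
        assert res.estimates["intercept"] == pytest.approx(0.0, abs=1e-8)
        assert res.estimates["x"] == pytest.approx(math.log(3), abs=1e-8)
        assert res.standard_errors["x"] == pytest.approx(
            math.sqrt(1 / 10 + 1 / 10 + 1 / 15 + 1 / 5), abs=1e-6
        )

    def test_constant_outcome_flagged(self):
        frame = pd.DataFrame(
            {"cluster_id": range(30), "member": 1, "y": 0, "x": np.linspace(0, 1, 30)}
        )
        res = tc.fit_logistic(tc.ClusteredDataset(frame), ["x"])
        assert not res.converged

    def test_null_slope_within_three_se(self):
        ds = singleton_dataset(50_000, 0.3, 0.0, np.random.default_rng(10))
        res = tc.fit_logistic(ds, ["x"])
        assert abs(res.estimates["x"]) < 3 * res.standard_errors["x"]


class TestPQL:
    def test_fixed_zero_variance_equals_logistic(self, death4_spec, death_model):
        sc = make_scenario(death4_spec, death_model, n_clusters=200, twin_fraction=0.2, seed=7)
        ds = tc.simulate_dataset(sc, 0)
        covs = list(death4_spec.coefficients)
        rp = tc.fit_glmm_pql(ds, covs, sigma2_fixed=0.0)
        rl = tc.fit_logistic(ds, covs)
        assert max(abs(rp.estimates[n] - rl.estimates[n]) for n in NAMES4) < 1e-6

    def test_singletons_only_variance_hits_boundary(self, death4_spec, death_model):
        sc = make_scenario(death4_spec, death_model, n_clusters=5000, twin_fraction=0.0, seed=5)
        ds = tc.simulate_dataset(sc, 0)
        covs = list(death4_spec.coefficients)
        rp = tc.fit_glmm_pql(ds, covs)
        rl = tc.fit_logistic(ds, covs)
        assert rp.variance_estimate == pytest.approx(0.0, abs=1e-6)
        assert max(abs(rp.estimates[n] - rl.estimates[n]) for n in NAMES4) < 1e-3

    def test_variance_attenuated_relative_to_agq(self):
        """PQL is known to shrink binary-data variance components."""
        rng = np.random.default_rng(50)
        pql_v, agq_v = [], []
        for _ in range(25):
            ds = twin_pairs_dataset(400, -0.5, 0.8, 1.0, rng)
            rp = tc.fit_glmm_pql(ds, ["x"])
            ra = tc.fit_glmm_agq(ds, ["x"])
            if rp.converged and ra.converged:
                pql_v.append(rp.variance_estimate)
                agq_v.append(ra.variance_estimate)
        assert len(pql_v) >= 20
        assert np.mean(pql_v) <= np.mean(agq_v)

    def test_oversized_cluster_raises(self):
        frame = pd.DataFrame(
            {"cluster_id": [1, 1, 1], "member": [1, 2, 3], "y": [0, 1, 0], "x": [0.0, 1.0, 2.0]}
        )
        with pytest.raises(tc.ValidationError):
            tc.fit_glmm_pql(tc.ClusteredDataset(frame), ["x"])


class TestAGQ:
    def test_fixed_zero_variance_equals_logistic(self, death4_spec, death_model):
        sc = make_scenario(death4_spec, death_model, n_clusters=200, twin_fraction=0.2, seed=7)
        ds = tc.simulate_dataset(sc, 0)
        covs = list(death4_spec.coefficients)
        ra = tc.fit_glmm_agq(ds, covs, sigma2_fixed=0.0)
        rl = tc.fit_logistic(ds, covs)
        assert max(abs(ra.estimates[n] - rl.estimates[n]) for n in NAMES4) < 1e-6

    def test_quadrature_matches_brute_force_small_dataset(self):
        rng = np.random.default_rng(3)
        ds = twin_pairs_dataset(4, -0.3, 0.6, 1.0, rng)
        params = {"intercept": -0.3, "x": 0.6}
        oracle = brute_force_loglik(ds, params, 1.0)
        ll25 = tc.marginal_loglik(ds, ["x"], params, 1.0, n_nodes=25)
        assert ll25 == pytest.approx(oracle, rel=1e-8)

    def test_node_count_convergence_ladder(self):
        """The 5-node study rule is a documented approximation; error
        shrinks by orders of magnitude as nodes are added."""
        rng = np.random.default_rng(8)
        errs = {k: [] for k in (5, 9, 15)}
        for _ in range(20):
            ds = twin_pairs_dataset(4, rng.uniform(-1, 1), rng.uniform(-1, 1), 1.0, rng)
            params = {"intercept": rng.uniform(-1, 1), "x": rng.uniform(-1, 1)}
            s2 = rng.uniform(0.25, 2.0)
            oracle = brute_force_loglik(ds, params, s2)
            for k in errs:
                errs[k].append(abs(tc.marginal_loglik(ds, ["x"], params, s2, n_nodes=k) - oracle) / abs(oracle))
        assert max(errs[5]) < 1e-3
        assert max(errs[9]) < 1e-5
        assert max(errs[15]) < 1e-7

    def test_loglik_nests_logistic(self, death4_spec, death_model):
        sc = make_scenario(death4_spec, death_model, n_clusters=150, twin_fraction=0.1, seed=19)
        covs = list(death4_spec.coefficients)
        for rep in range(3):
            ds = tc.simulate_dataset(sc, rep)
            ra = tc.fit_glmm_agq(ds, covs)
            rl = tc.fit_logistic(ds, covs)
            if ra.converged and rl.converged:
                assert ra.diagnostics["loglik"] >= rl.diagnostics["loglik"] - 1e-6

    def test_refit_is_deterministic(self, death4_spec, death_model):
        sc = make_scenario(death4_spec, death_model, n_clusters=150, twin_fraction=0.1, seed=2)
        ds = tc.simulate_dataset(sc, 0)
        covs = list(death4_spec.coefficients)
        a, b = tc.fit_glmm_agq(ds, covs), tc.fit_glmm_agq(ds, covs)
        assert a.estimates == b.estimates
        assert a.variance_estimate == b.variance_estimate

    def test_recovery_smoke(self):
        rng = np.random.default_rng(77)
        ds = twin_pairs_dataset(2000, -0.5, 0.8, 1.0, rng)
        res = tc.fit_glmm_agq(ds, ["x"])
        assert res.converged
        assert res.estimates["x"] == pytest.approx(0.8, abs=3 * res.standard_errors["x"])
        assert res.variance_estimate == pytest.approx(1.0, abs=0.5)

    def test_negative_fixed_variance_raises(self):
        ds = twin_pairs_dataset(10, 0.0, 0.5, 1.0, np.random.default_rng(0))
        with pytest.raises(tc.ValidationError):
            tc.fit_glmm_agq(ds, ["x"], sigma2_fixed=-1.0)


class TestGEE:
    def test_all_singletons_equals_robust_logistic(self, death4_spec, death_model):
        sc = make_scenario(death4_spec, death_model, n_clusters=400, twin_fraction=0.0, seed=8)
        ds = tc.simulate_dataset(sc, 0)
        covs = list(death4_spec.coefficients)
        rg = tc.fit_gee_exchangeable(ds, covs)
        rl = tc.fit_logistic(ds, covs)
        assert rg.diagnostics["working_correlation"] == 0.0
        assert max(abs(rg.estimates[n] - rl.estimates[n]) for n in NAMES4) < 1e-6
        X = np.column_stack([np.ones(len(ds.frame))] + [ds.frame[c] for c in covs])
        hc0 = sm.Logit(ds.frame["y"], X).fit(disp=0, cov_type="HC0")
        np.testing.assert_allclose(
            [rg.standard_errors[n] for n in NAMES4], hc0.bse, atol=1e-6
        )

    def test_duplicated_pairs_boundary_correlation(self):
        rng = np.random.default_rng(4)
        n = 400
        x = rng.normal(size=n)
        y = rng.binomial(1, 1 / (1 + np.exp(-(0.2 + 0.8 * x))))
        dup = tc.ClusteredDataset(
            pd.DataFrame(
                {
                    "cluster_id": np.repeat(np.arange(n), 2),
                    "member": np.tile([1, 2], n),
                    "y": np.repeat(y, 2),
                    "x": np.repeat(x, 2),
                }
            )
        )
        one = tc.ClusteredDataset(
            pd.DataFrame({"cluster_id": np.arange(n), "member": 1, "y": y, "x": x})
        )
        rg = tc.fit_gee_exchangeable(dup, ["x"])
        rl = tc.fit_logistic(one, ["x"])
        # the moment estimate is pinned at the stability clip just below 1
        assert rg.diagnostics["working_correlation"] >= 0.95
        assert max(abs(rg.estimates[k] - rl.estimates[k]) for k in rg.estimates) < 1e-6

    def test_matches_statsmodels_gee_oracle(self, death4_spec_v2, death_model):
        """Independent cross-check: point estimates, sandwich SEs and the
        working correlation agree with statsmodels GEE on pairs-rich data
        (enough pairs for the same degrees-of-freedom convention)."""
        import warnings

        sc = make_scenario(death4_spec_v2, death_model, n_clusters=500,
                           twin_fraction=0.3, seed=21)
        ds = tc.simulate_dataset(sc, 0)
        covs = list(death4_spec_v2.coefficients)
        ours = tc.fit_gee_exchangeable(ds, covs)
        frame = ds.frame.sort_values(["cluster_id", "member"])
        X = np.column_stack([np.ones(len(frame))] + [frame[c] for c in covs])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cov_struct = sm.cov_struct.Exchangeable()
            res = sm.GEE(
                frame["y"].to_numpy(float), X, groups=frame["cluster_id"].to_numpy(),
                family=sm.families.Binomial(), cov_struct=cov_struct,
            ).fit(maxiter=100, ctol=1e-11)
        for i, n in enumerate(NAMES4):
            assert ours.estimates[n] == pytest.approx(res.params[i], abs=1e-8)
            assert ours.standard_errors[n] == pytest.approx(res.bse[i], abs=1e-8)
        assert ours.diagnostics["working_correlation"] == pytest.approx(
            float(np.atleast_1d(cov_struct.dep_params)[0]), abs=1e-8
        )

    def test_attenuation_consistent_with_conversion_formula(self, death4_spec_v2, death_model):
        """Large-sample GEE slope sits near the converted marginal target.

        The closed-form conversion is an approximation, so agreement is
        asserted to ~5% of the coefficient, not to Monte-Carlo precision.
        """
        sc = make_scenario(
            death4_spec_v2, death_model, n_clusters=40_000, twin_fraction=0.1, seed=3
        )
        ds = tc.simulate_dataset(sc, 0)
        covs = list(death4_spec_v2.coefficients)
        rg = tc.fit_gee_exchangeable(ds, covs)
        target = tc.convert_to_marginal(death4_spec_v2.coefficients["bweight"], 2.0)
        conditional = death4_spec_v2.coefficients["bweight"]
        # attenuated away from the conditional slope, toward the target
        assert abs(rg.estimates["bweight"]) < abs(conditional)
        assert rg.estimates["bweight"] == pytest.approx(target, rel=0.05)


class TestCrossMethodAgreement:
    def test_iid_data_all_methods_agree(self, death4_spec, death_model):
        spec = death4_spec.with_(random_intercept_variance=0.0)
        sc = make_scenario(spec, death_model, n_clusters=5000, twin_fraction=0.0, seed=15)
        ds = tc.simulate_dataset(sc, 0)
        covs = list(spec.coefficients)
        fits = {
            "logistic": tc.fit_logistic(ds, covs),
            "pql": tc.fit_glmm_pql(ds, covs),
            "agq": tc.fit_glmm_agq(ds, covs),
            "gee": tc.fit_gee_exchangeable(ds, covs),
        }
        for name in NAMES4:
            vals = [f.estimates[name] for f in fits.values()]
            se = fits["logistic"].standard_errors[name]
            assert max(vals) - min(vals) < 3 * se

    def test_standard_errors_positive(self, death4_spec, death_model):
        sc = make_scenario(death4_spec, death_model, n_clusters=300, twin_fraction=0.2, seed=1)
        ds = tc.simulate_dataset(sc, 0)
        covs = list(death4_spec.coefficients)
        for fitter in (tc.fit_logistic, tc.fit_glmm_pql, tc.fit_glmm_agq, tc.fit_gee_exchangeable):
            res = fitter(ds, covs)
            assert all(v > 0 for v in res.standard_errors.values())


class TestDivergenceFilter:
    def _result(self, estimates):
        return FitResult(
            method="gee",
            estimates=estimates,
            standard_errors={k: 1.0 for k in estimates},
            variance_estimate=None,
            converged=True,
            n_iterations=5,
        )

    def test_below_threshold_unchanged(self):
        res = self._result({"intercept": 0.2, "x": -1.5})
        assert tc.apply_divergence_filter(res) is res

    def test_huge_estimate_discards_everything(self):
        res = tc.apply_divergence_filter(self._result({"intercept": 1e12, "x": 0.1}))
        assert not res.converged
        assert all(np.isnan(v) for v in res.estimates.values())
        assert all(np.isnan(v) for v in res.standard_errors.values())

    def test_exactly_threshold_passes(self):
        res = self._result({"intercept": 1000.0, "x": -1000.0})
        assert tc.apply_divergence_filter(res) is res

    def test_idempotent(self):
        filtered = tc.apply_divergence_filter(self._result({"intercept": 2000.0}))
        again = tc.apply_divergence_filter(filtered)
        assert not again.converged
        assert all(np.isnan(v) for v in again.estimates.values())
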