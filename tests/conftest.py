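import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import twinclust as tc

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def death_model():
    return tc.load_covariate_model("death")


@pytest.fixture(scope="session")
def o2dep_model():
    return tc.load_covariate_model("o2dep")


@pytest.fixture(scope="session")
def death4_spec():
    """Death/4-covariate spec with its reference variance, calibrated."""
    return tc.calibrated_spec("death", 4)


@pytest.fixture(scope="session")
def death4_spec_v2():
    """Death/4-covariate spec at random-intercept variance 2, calibrated."""
    return tc.calibrated_spec("death", 4, variance=2.0)


def make_scenario(spec, model, n_clusters=150, twin_fraction=0.1, n_reps=1, seed=0):
    return tc.Scenario(
        n_clusters=n_clusters,
        twin_fraction=twin_fraction,
        outcome_spec=spec,
        covariate_model=model,
        n_reps=n_reps,
        master_seed=seed,
    )


@pytest.fixture
def scenario_factory():
    return make_scenario


def twin_pairs_dataset(n_pairs, beta0, beta1, sigma2, rng):
    """Minimal hand-rolled generator: pairs with one binary covariate."""
    u = rng.normal(0.0, np.sqrt(sigma2), n_pairs)
    x = rng.integers(0, 2, (n_pairs, 2)).astype(float)
    eta = beta0 + beta1 * x + u[:, None]
    y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta)))
    frame = pd.DataFrame(
        {
            "cluster_id": np.repeat(np.arange(1, n_pairs + 1), 2),
            "member": np.tile([1, 2], n_pairs),
            "y": y.reshape(-1),
            "x": x.reshape(-1),
        }
    )
    return tc.ClusteredDataset(frame)


def singleton_dataset(n, beta0, beta1, rng):
    x = rng.normal(size=n)
    y = rng.binomial(1, 1.0 / (1.0 + np.exp(-(beta0 + beta1 * x))))
    frame = pd.DataFrame(
        {"cluster_id": np.arange(1, n + 1), "member": 1, "y": y, "x": x}
    )
    return tc.ClusteredDataset(frame)
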