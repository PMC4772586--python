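import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.special import expit

import dtmediate as dm
from dtmediate.datasets import colon_coefficient_table, colon_model_spec

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def simulate_one_covariate(
    n, J, beta0, kappa, seed=None, rng=None, x=None
):
    """Single-covariate discrete-time cohort; ``kappa`` may be scalar or a
    per-period sequence (used to break proportionality)."""
    rng = rng or np.random.default_rng(seed)
    if x is None:
        x = rng.standard_normal(n)
    kappa = np.broadcast_to(np.asarray(kappa, dtype=float), (J,))
    h = expit(beta0 + np.outer(x, kappa))
    draws = rng.random((n, J)) < h
    any_e = draws.any(axis=1)
    t = np.where(any_e, draws.argmax(axis=1) + 1, J)
    return [
        dm.SurvivalRecord(i, int(t[i]), int(any_e[i]), {"x": float(x[i])})
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def sim_records():
    """A moderate single-covariate cohort reused across hazard-model tests."""
    return simulate_one_covariate(n=600, J=10, beta0=-2.0, kappa=0.5, seed=42)


@pytest.fixture(scope="session")
def sim_table(sim_records):
    return dm.expand_person_period(sim_records, J_max=10)


@pytest.fixture(scope="session")
def colon_spec():
    return colon_model_spec()


@pytest.fixture(scope="session")
def colon_coefficients():
    return dm.CoefficientTable(colon_coefficient_table())


@pytest.fixture(scope="session")
def colon_cohort():
    """One synthetic cohort drawn from the published generative system."""
    cfg = dm.SyntheticConfig(n=2000, seed=2024)
    frame, manifest = dm.simulate_frame(cfg)
    return cfg, frame, manifest
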