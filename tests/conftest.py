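import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import neurodim as nd

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def linear_cohort():
    """Default linear-truth cohort at the reference sample size."""
    return nd.generate_cohort(nd.CohortConfig(n_cases=400, seed=101))


@pytest.fixture(scope="session")
def null_cohort():
    return nd.generate_cohort(nd.CohortConfig(n_cases=400, seed=202, effect_mode="null"))


@pytest.fixture(scope="session")
def big_null_cohort():
    """Large cohort for moment-convergence checks."""
    return nd.generate_cohort(
        nd.CohortConfig(n_cases=50_000, seed=303, effect_mode="null")
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def exact_two_factor_cov():
    """Population covariance of a two-factor model: lambda=0.7, phi=0.5."""
    spec = nd.correlated_factors_spec()
    lam = np.zeros((9, 2))
    for i, dom in enumerate(nd.DOMAIN_COLUMNS):
        lam[i, spec.factors.index(spec.pattern[dom])] = 0.7
    phi = np.array([[1.0, 0.5], [0.5, 1.0]])
    psi = np.full(9, 1 - 0.49)
    return lam @ phi @ lam.T + np.diag(psi)


def make_predictor_table(rng, n, k=10):
    cols = [f"x{i}" for i in range(k)]
    return pd.DataFrame(rng.standard_normal((n, k)), columns=cols)
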