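import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import binmrf as bm

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def m6():
    return bm.preset_structure("m6")


@pytest.fixture(scope="session")
def m6_truth(m6):
    return bm.true_graph(m6)


@pytest.fixture(scope="session")
def paper19():
    return bm.preset_structure("paper19")


@pytest.fixture(scope="session")
def paper19_truth(paper19):
    return bm.true_graph(paper19)


@pytest.fixture(scope="session")
def m6_data_1000(m6):
    """One n=1000 draw from the six-variable benchmark, shared across tests."""
    return bm.gibbs_sample(m6, 1000, seed=42)


@pytest.fixture(scope="session")
def logistic_problem():
    """A small standardized logistic problem with one null predictor."""
    rng = np.random.default_rng(7)
    n, m = 80, 3
    X = rng.normal(size=(n, m))
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    beta = np.array([1.2, -0.7, 0.0])
    from scipy.special import expit

    y = (rng.random(n) < expit(0.4 + X @ beta)).astype(float)
    return y, X
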