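import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from covforest import SupervisedSample
from covforest.params import ForestParams

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_sample(rng):
    """60 rows, 3 numeric covariates, bivariate response with an X1-driven
    covariance regime change (clear signal for splitting)."""
    n = 60
    X = rng.standard_normal((n, 3))
    Y = np.empty((n, 2))
    hi = X[:, 0] > 0
    c_hi = np.array([[1.0, 0.9], [0.9, 1.0]])
    c_lo = np.array([[1.0, -0.5], [-0.5, 1.0]])
    z = rng.standard_normal((n, 2))
    Y[hi] = z[hi] @ np.linalg.cholesky(c_hi).T
    Y[~hi] = z[~hi] @ np.linalg.cholesky(c_lo).T
    return SupervisedSample(X=X, Y=Y, is_categorical=np.zeros(3, dtype=bool))


@pytest.fixture
def small_params():
    return ForestParams(n_trees=30, nodesize=10, seed=11)
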