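import numpy as np
import pytest

from excesshits import Dataset, fit_ols_many


@pytest.fixture
def toy_dataset() -> Dataset:
    """4-point hand-checkable regression: Y = x + e with e orthogonal to [1, x]."""
    x = np.array([-1.5, -0.5, 0.5, 1.5])
    e = np.array([1.0, -1.0, -1.0, 1.0])
    return Dataset(X=np.column_stack([np.ones(4), x]), Y=(x + e)[:, None])


@pytest.fixture
def toy_fit(toy_dataset):
    return fit_ols_many(toy_dataset)


@pytest.fixture
def random_dataset():
    """Factory for small random datasets with covariates."""

    def make(N=20, C=3, W=4, seed=0, beta=0.0):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(N), rng.standard_normal((N, C - 1))])
        Y = beta * X[:, [1]] + rng.standard_normal((N, W))
        return Dataset(X=X, Y=Y, exposure_index=1)

    return make
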