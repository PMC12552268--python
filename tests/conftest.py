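import numpy as np
import pytest

import dplasso as dp


def balanced_labels(rng: np.random.Generator, N: int, K: int) -> np.ndarray:
    """Random labels guaranteed to give every class at least two members."""
    y = np.concatenate([np.repeat(np.arange(K), 2), rng.integers(0, K, N - 2 * K)])
    rng.shuffle(y)
    return y


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def four_point():
    """The worked 4-sample, 2-class example used throughout the weight tests."""
    return np.array([0.0, 1.0, 2.0, 3.0]), np.array([0, 0, 1, 1])


@pytest.fixture
def small_data(rng):
    """A 60 x 5 three-class dataset with two informative features."""
    N, p, K = 60, 5, 3
    y = balanced_labels(rng, N, K)
    X = rng.standard_normal((N, p))
    X[:, 0] += 1.5 * (y == 0)
    X[:, 1] -= 1.5 * (y == 2)
    return dp.LabeledDataset(X=X, y=y)
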