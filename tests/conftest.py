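import numpy as np
import pytest

from nuclinker import FeatureMatrix


def make_matrix(values, labels, names=None, ids=None) -> FeatureMatrix:
    values = np.asarray(values, dtype=float)
    if names is None:
        names = [f"F{j + 1}" for j in range(values.shape[1])]
    return FeatureMatrix(values, np.asarray(labels), list(names), list(ids or []))


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)


@pytest.fixture
def toy_matrix():
    """8 samples, 3 features: F1 informative, F2 = F1 copy, F3 weak independent.

    Values discretize (t=1, sample std) to
      F1: [H,H,M,M,L,L,M,M], F2 identical, F3: [M,M,H,M,M,M,L,M]
    against labels [1,1,1,1,2,2,2,2].
    """
    f1 = [10.0, 10.0, 0.0, 0.0, -10.0, -10.0, 0.0, 0.0]
    f3 = [0.0, 0.0, 10.0, 0.0, 0.0, 0.0, -10.0, 0.0]
    values = np.column_stack([f1, f1, f3])
    # point-biserial style matrices require non-negative values only for
    # counts; mRMR discretization does not, so raw signed values are fine
    values = values - values.min()
    labels = [1, 1, 1, 1, 2, 2, 2, 2]
    return make_matrix(values, labels)


@pytest.fixture
def random_matrix(rng):
    n, f = 60, 6
    values = rng.poisson(3.0, size=(n, f)) / 100.0
    labels = np.where(rng.random(n) < 0.5, 1, 2)
    labels[:2] = [1, 2]  # force both classes
    return make_matrix(values, labels)
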