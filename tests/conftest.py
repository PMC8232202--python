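import numpy as np
import pytest

from rarank import FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def make_table():
    """Factory for random two-class Gaussian tables."""

    def _make(n1=4, n2=6, p=6, shift=1.0, seed=0):
        g = np.random.default_rng(seed)
        X = np.vstack([g.normal(shift, 1.0, (n1, p)),
                       g.normal(0.0, 1.0, (n2, p))])
        y = np.array([1] * n1 + [0] * n2)
        return FeatureTable(X, y)

    return _make


@pytest.fixture
def separable_table():
    """Feature 0 separates the classes perfectly; feature 1 is pure noise."""
    g = np.random.default_rng(3)
    n1, n2 = 10, 14
    x_sep = np.concatenate([g.uniform(2.0, 3.0, n1), g.uniform(-1.0, 0.0, n2)])
    x_noise = g.normal(0.0, 1.0, n1 + n2)
    X = np.column_stack([x_sep, x_noise])
    return FeatureTable(X, np.array([1] * n1 + [0] * n2))
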