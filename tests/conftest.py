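import numpy as np
import pytest

from logsumlr import LabeledDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def separable_toy(rng):
    """Linearly separable 2-feature problem (40 samples)."""
    X = rng.standard_normal((40, 2))
    y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(int)
    return LabeledDataset(X, y, ["f1", "f2"])


@pytest.fixture
def noisy_toy(rng):
    """Non-separable 5-feature problem for convergence/fixed-point checks."""
    X = rng.standard_normal((80, 5))
    eta = 1.2 * X[:, 0] - 0.8 * X[:, 1]
    y = (rng.random(80) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return LabeledDataset(X, y, [f"f{i}" for i in range(1, 6)])
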