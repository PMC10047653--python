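import numpy as np
import pytest

from bhsic import CISample, SimConfig, TestConfig, generate


def naive_hsic(k_x: np.ndarray, k_y: np.ndarray) -> float:
    """Independent O(n^3) oracle: explicit H-matrix products for the trace."""
    n = k_x.shape[0]
    h = np.eye(n) - np.ones((n, n)) / n
    return float(np.trace(k_x @ h @ k_y @ h) / (n * n))


def wcss(z: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster sum of squared distances to centroids."""
    total = 0.0
    for lab in np.unique(labels):
        pts = z[labels == lab]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


@pytest.fixture
def rng():
    return np.random.default_rng(20230425)


@pytest.fixture
def small_sample(rng):
    """An n=30 sample with genuine x-y dependence modulated by z."""
    z = rng.standard_normal((30, 2))
    x = z[:, 0] + 0.3 * rng.standard_normal(30)
    y = x + 0.3 * rng.standard_normal(30)
    return CISample(x, y, z)


@pytest.fixture
def quick_config():
    """A short but real test configuration for orchestration tests."""
    return TestConfig(n_bootstrap=50, seed=11)


@pytest.fixture
def null_sample_dz1():
    """One Model 2 dataset under the null (c=0, d_z=1)."""
    return generate(SimConfig("postnonlinear", 200, 1, 0.0, seed=404))
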