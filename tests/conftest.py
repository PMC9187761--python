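import numpy as np
import pytest

from lshgan import MixtureSpec, make_gaussian_mixture


@pytest.fixture(scope="session")
def line_points() -> np.ndarray:
    """Two well-separated runs of 1-D points, embedded in 5-D."""
    x = np.zeros((6, 5))
    x[:, 0] = [0.0, 1.0, 2.0, 10.0, 11.0, 12.0]
    return x


@pytest.fixture(scope="session")
def small_mixture():
    """Reduced 2-class Gaussian mixture (100 x 50) for fast tests."""
    return make_gaussian_mixture(MixtureSpec(n_samples=100, n_features=50, seed=11))


@pytest.fixture(scope="session")
def full_mixture():
    """The full-scale benchmark mixture (100 x 1000)."""
    return make_gaussian_mixture(MixtureSpec(seed=11))
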