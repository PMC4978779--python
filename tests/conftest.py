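import numpy as np
import pytest

from pofm import ModelSpec, OrdinalMatrix, Parameters


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_bicluster():
    """A tiny 4x3, q=3 instance with fixed (R=2, C=2) parameters."""
    rng = np.random.default_rng(7)
    data = OrdinalMatrix(rng.integers(1, 4, size=(4, 3)), q=3)
    spec = ModelSpec("clustered", "clustered", R=2, C=2)
    params = Parameters(
        mu=np.array([-0.5, 0.7]),
        alpha=np.array([0.0, 1.0]),
        beta=np.array([0.0, -0.8]),
        pi=np.array([0.3, 0.7]),
        kappa=np.array([0.6, 0.4]),
    )
    return data, spec, params


@pytest.fixture
def small_row_mixture():
    """A 3x2 binary-response instance with a two-component row mixture."""
    rng = np.random.default_rng(3)
    data = OrdinalMatrix(rng.integers(1, 3, size=(3, 2)), q=2)
    spec = ModelSpec("clustered", "single", R=2)
    params = Parameters(
        mu=np.array([0.3]),
        alpha=np.array([0.0, 1.2]),
        beta=np.zeros(1),
        pi=np.array([0.4, 0.6]),
    )
    return data, spec, params
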