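import warnings

import numpy as np
import pytest

from endevs.decomposition import PooledSample
from endevs.deviance import deviant_patterns

# GP hyperparameter optimization on tiny fixtures routinely brushes its
# search bounds; that is expected and not what these tests probe.
warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")
warnings.filterwarnings("ignore", message=".*ConvergenceWarning.*")
try:
    from sklearn.exceptions import ConvergenceWarning

    warnings.filterwarnings("ignore", category=ConvergenceWarning)
except ImportError:  # pragma: no cover
    pass


def random_pooled_sample(rng, equal_weights=False):
    """A random but valid PooledSample: sparse magnitudes -> patterns."""
    n = int(rng.integers(2, 11))
    m = int(rng.integers(2, 16))
    z = np.abs(rng.standard_normal((n, m)))
    mask = rng.random((n, m)) < 0.4
    z[mask] = 0.0
    z[np.arange(n), rng.integers(0, m, n)] += 0.5  # every row has signal
    c = float(rng.choice([0.2, 0.5, 1.0]))
    psi, _ = deviant_patterns(z, "absolute-top", c)
    weights = None if equal_weights else rng.uniform(0.1, 2.0, psi.shape[0])
    return PooledSample(psi, weights, c=c, mode="absolute-top")


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
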