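import numpy as np
import pytest

from tractokit import phantom as ph


@pytest.fixture(scope="session")
def default_phantom():
    """The standard two-bundle + 100-distractor phantom (built once)."""
    return ph.make_phantom(ph.default_phantom_spec(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_polyline(rng, n_points=7, scale=10.0):
    """A random streamline: cumulative random steps, guaranteed non-degenerate."""
    steps = rng.normal(0.0, scale / n_points, size=(n_points - 1, 3))
    steps[np.linalg.norm(steps, axis=1) < 1e-3] += 0.1
    return np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
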