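import numpy as np
import pytest

from ssakit.landmark_io import LandmarkSample
from ssakit.synthetic_data import ShapePopulationSpec, simulate_sample, template_cc_shape


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def template():
    return template_cc_shape()


def random_configuration(rng, k=16, scale=1.0):
    """A generic non-degenerate k x 2 configuration."""
    while True:
        coords = rng.normal(0.0, scale, size=(k, 2))
        d = coords[:, None, :] - coords[None, :, :]
        r = np.sqrt((d**2).sum(-1))
        np.fill_diagonal(r, np.inf)
        if r.min() > 1e-3:
            return coords


@pytest.fixture
def small_sample(rng):
    """10 specimens, 16 landmarks, mild noise around the template arch."""
    spec = ShapePopulationSpec(n=10, sigma=0.02, seed=99)
    return simulate_sample(spec, group=1)


@pytest.fixture
def two_group_samples():
    """A homogeneous two-group pair, n=41 each."""
    spec = ShapePopulationSpec(n=41, sigma=0.02, seed=7)
    return simulate_sample(spec, group=1), simulate_sample(spec, group=2)


@pytest.fixture
def sample_from_array():
    def _make(coords, label="g"):
        return LandmarkSample.from_array(label, np.asarray(coords, dtype=float))

    return _make
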