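import numpy as np
import pytest

from lgkinetics import synthetic
from lgkinetics.trackio import IntensityTrack, RunConfig


@pytest.fixture(scope="session")
def geometry():
    return synthetic.default_geometry()


@pytest.fixture()
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def random_track(rng, cell_id="t", n=None):
    """A random valid track (positive finite intensities, ascending times)."""
    n = n or int(rng.integers(5, 40))
    frames = np.arange(n)
    return IntensityTrack(
        cell_id=cell_id, frames=frames, times_min=frames * 0.25,
        green=rng.uniform(0.0, 200.0, n), red=rng.uniform(0.0, 200.0, n))
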