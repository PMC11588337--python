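import numpy as np
import pytest

from popazi import AzimuthGrid, ResponseDataset

ANGLES = np.arange(-90, 91, 15, dtype=float)


@pytest.fixture(scope="session")
def grid():
    return AzimuthGrid()


@pytest.fixture
def small_dataset(grid):
    """13 azimuths x 3 reps x 4 units, deterministic responses."""
    rng = np.random.default_rng(7)
    labels = np.repeat(ANGLES, 3)
    responses = rng.gamma(2.0, 0.5, size=(labels.size, 4))
    return ResponseDataset(responses=responses, labels=labels, grid=grid)


@pytest.fixture
def separable_dataset(grid):
    """Noiseless dataset: a distinct constant pattern per azimuth."""
    rng = np.random.default_rng(3)
    patterns = rng.uniform(1.0, 10.0, size=(13, 5))
    labels = np.repeat(ANGLES, 3)
    responses = np.vstack([np.tile(patterns[k], (3, 1)) for k in range(13)])
    return ResponseDataset(responses=responses, labels=labels, grid=grid)
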