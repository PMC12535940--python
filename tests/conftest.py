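import warnings

import numpy as np
import pytest

from retrohab.core import Grid
from retrohab.synthetic import generate_world, render_scenes


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def flat_grid():
    return Grid(np.full((8, 8), 0.25), nodata=None)


@pytest.fixture(scope="session")
def small_world():
    """A 48x48 world with 4 years, shared across read-only tests."""
    return generate_world(seed=7, shape=(48, 48), years=[2001, 2002, 2003, 2004])


@pytest.fixture(scope="session")
def small_scenes(small_world):
    return render_scenes(small_world, scenes_per_season=2, noise_sd=0.005, cloud_frac=0.08)
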