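import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from slpru import EndmemberMatrix, SpectralImage  # noqa: E402
from slpru.simulate import synth_endmembers  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20230325)


@pytest.fixture(scope="session")
def small_M():
    """8 channels x 4 well-conditioned synthetic endmembers."""
    return synth_endmembers(8, 4, width=0.25)


@pytest.fixture(scope="session")
def M13():
    """32 channels x 13 endmembers, the full-instrument layout."""
    return synth_endmembers(32, 13)


@pytest.fixture
def ramp_image():
    C, H, W = 2, 4, 5
    cube = np.arange(C * H * W, dtype=float).reshape(C, H, W)
    return SpectralImage(cube)


def random_endmembers(rng, C, R):
    """Strictly positive random unit-sum columns (full column rank a.s.)."""
    M = rng.uniform(0.1, 1.0, (C, R))
    return EndmemberMatrix.from_columns(M)
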