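import numpy as np
import pytest

from oildrop.grid import SpectralGrid, TrophicScenario
from oildrop.water import build_water_iops


@pytest.fixture(scope="session")
def ci_grid() -> SpectralGrid:
    """Minimal grid carrying the color-index bands."""
    return SpectralGrid(np.array([440.0, 445.0, 555.0, 670.0]))


@pytest.fixture(scope="session")
def oligotrophic_water(ci_grid):
    return build_water_iops(TrophicScenario(0.1), ci_grid)


@pytest.fixture(scope="session")
def reduced_grid() -> SpectralGrid:
    from oildrop.pipeline import REDUCED_BANDS

    return SpectralGrid(np.array(REDUCED_BANDS))
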