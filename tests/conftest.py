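import numpy as np
import pytest
from shapely.geometry import box

from beeranges.fixtures import load_table1
from beeranges.io import LandUseMap


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mosaic():
    """Four labeled squares tiling a 200 x 100 window (plus a gap row)."""
    return LandUseMap(
        [
            box(0, 0, 100, 100),
            box(100, 0, 200, 100),
            box(0, 100, 100, 150),
            box(100, 100, 200, 150),
        ],
        ["blueberry", "plantation", "semi_natural", "other_fruits"],
    )
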