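import numpy as np
import pytest

from oncodict import simulate
from oncodict.band_grid import build_virtual_grid


@pytest.fixture(scope="session")
def toy_bands():
    return simulate.toy_cytoband_map()


@pytest.fixture(scope="session")
def toy_grid(toy_bands):
    return build_virtual_grid(toy_bands, n_per_band=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
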