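import numpy as np
import pytest

from cycleharm import Volume, TissueSegmentation, generate_phantom


@pytest.fixture(scope="session")
def phantom40():
    """One deterministic mid-age phantom at test scale."""
    return generate_phantom(age=40.0, size=48, seed=7)


@pytest.fixture(scope="session")
def small_phantom():
    """Smallest admissible phantom, for cheap structural tests."""
    return generate_phantom(age=35.0, size=32, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def block_volume():
    """Hand-built two-tissue block volume with known statistics."""
    data = np.zeros((10, 10, 10))
    gm = np.zeros((10, 10, 10))
    wm = np.zeros((10, 10, 10))
    gen = np.random.default_rng(0)
    data[:5] = gen.normal(300.0, 30.0, size=(5, 10, 10))
    data[5:] = gen.normal(600.0, 30.0, size=(5, 10, 10))
    gm[:5] = 1.0
    wm[5:] = 1.0
    vol = Volume(data, np.ones((10, 10, 10), bool))
    seg = TissueSegmentation(gm=gm, wm=wm, csf=np.zeros_like(gm))
    return vol, seg
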