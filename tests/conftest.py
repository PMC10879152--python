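import numpy as np
import pytest

from somatosim import afferent_sim as af
from somatosim import stim_encoding as se
from somatosim import synthetic_ephys as sy


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ramp_stimulus():
    return af.make_ramp_and_hold(noise_fraction=0.0)


@pytest.fixture(scope="session")
def small_population():
    return af.build_population("FULL", 40, seed=7)


@pytest.fixture(scope="session")
def small_geometry():
    return sy.ProbeGeometry(8, "linear", 100.0)


@pytest.fixture(scope="session")
def tonic_train():
    return se.make_tonic(50.0, 2.0)
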