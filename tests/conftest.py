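import numpy as np
import pytest

from paramhip.contact import MaterialConfig
from paramhip.geometry import build_model
from paramhip.params import preset


@pytest.fixture(scope="session")
def p1():
    return preset("P1")


@pytest.fixture(scope="session")
def p2():
    return preset("P2")


@pytest.fixture(scope="session")
def geo_p1(p1):
    """P1 at default density in the canonical (unmirrored) frame."""
    return build_model(p1, mirror=False)


@pytest.fixture(scope="session")
def geo_p1_mirrored(p1):
    """P1 as a left hip (mirrored through the sagittal plane)."""
    return build_model(p1)


@pytest.fixture(scope="session")
def geo_p2(p2):
    return build_model(p2)


@pytest.fixture(scope="session")
def geo_p1_coarse(p1):
    return build_model(p1, n_rings=24, mirror=False)


@pytest.fixture(scope="session")
def material():
    return MaterialConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
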