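import numpy as np
import pytest

from corralmc import build_geometry
from corralmc.kinetics import RateTable


@pytest.fixture(scope="session")
def nominal_geometry():
    """240 nm box, 6 nm lattice, one centred 48 nm high-density domain."""
    return build_geometry(240.0, 6.0, [((96.0, 96.0), 48.0)])


@pytest.fixture(scope="session")
def nominal_rates():
    return RateTable()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
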