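import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from quantalca.gating import GatingRates
from quantalca.occupancy import LigandParams, OccupancyModel

IP3_KD = 794.0


@pytest.fixture(scope="session")
def ip3():
    return LigandParams(name="IP3", K_D=IP3_KD, assay_context="CLM 22C")


@pytest.fixture(scope="session")
def hek_model(ip3):
    """HEK-IP3R1 cell: 49,146 receptors."""
    return OccupancyModel(ligand=ip3, receptors_per_cell=49146)


@pytest.fixture(scope="session")
def wt_model(ip3):
    """Wild-type HEK cell: 9,101 receptors."""
    return OccupancyModel(ligand=ip3, receptors_per_cell=9101)


@pytest.fixture(scope="session")
def rates():
    return GatingRates()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
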