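import numpy as np
import pytest

from dicentra import RejoiningKernel, SimulationConfig, build_nucleus
from dicentra.calibration import IonCategory
from dicentra.database import CategoryTable, DicentricDatabase, PhotonReference


@pytest.fixture
def config():
    return SimulationConfig()


@pytest.fixture
def nucleus(config):
    return build_nucleus(config, seed=1)


@pytest.fixture
def kernel():
    return RejoiningKernel()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_db():
    """Hand-written LQ database: fast, deterministic, MC-free."""
    tables = {
        IonCategory.PROTON: CategoryTable(
            np.array([2.5, 15.0, 30.0]),
            np.array([0.05, 0.15, 0.30]),
            np.array([0.045, 0.050, 0.055]),
        ),
        IonCategory.HELIUM: CategoryTable(
            np.array([5.0, 60.0, 110.0]),
            np.array([0.06, 0.20, 0.40]),
            np.array([0.040, 0.035, 0.020]),
        ),
        IonCategory.HEAVY: CategoryTable(
            np.array([5.0, 80.0, 150.0]),
            np.array([0.05, 0.30, 0.55]),
            np.array([0.045, 0.030, 0.015]),
        ),
    }
    return DicentricDatabase(
        tables=tables, photon=PhotonReference(), metadata={"origin": "toy"}
    )
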