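import numpy as np
import pytest

from mfsim.fluids import BLOOD_CY, FluidSpec
from mfsim.lbm import make_lattice

# the solvers guard their own divisions; numpy warnings from masked
# where() branches are expected and not collected as errors
np.seterr(all="ignore")


@pytest.fixture(scope="session")
def d2q9():
    return make_lattice("D2Q9")


@pytest.fixture(scope="session")
def d3q19():
    return make_lattice("D3Q19")


@pytest.fixture(scope="session")
def blood():
    return BLOOD_CY


@pytest.fixture(scope="session")
def blood_fluid():
    return FluidSpec(density=1060.0, carreau_yasuda=BLOOD_CY)


@pytest.fixture(scope="session")
def water_fluid():
    return FluidSpec(density=1000.0, viscosity=1e-3)
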