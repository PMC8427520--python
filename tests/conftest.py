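import numpy as np
import pytest

from sumd.engine import LangevinEngine
from sumd.fixtures import generate_fixture


@pytest.fixture(scope="session")
def engine():
    return LangevinEngine()


@pytest.fixture(scope="session")
def funnel():
    """funnel_binding fixture: ligand 32 A out, 4 fixed receptor beads."""
    return generate_fixture("funnel_binding", seed=1)


@pytest.fixture(scope="session")
def bound():
    """bound_complex fixture: ligand seated in the site, solvent bath."""
    return generate_fixture("bound_complex", seed=1)


@pytest.fixture(scope="session")
def double_well():
    return generate_fixture("double_well_1d", seed=0)


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.PCG64(1234))
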