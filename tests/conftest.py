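import numpy as np
import pytest

from hapthermal.geometry import build_unit_cell
from hapthermal.synthetic import make_toy_crystal, make_velocity_ensemble


@pytest.fixture(scope="session")
def unit_cell():
    return build_unit_cell()


@pytest.fixture(scope="session")
def toy():
    """Small ionic crystal with two tagged O-H diatomics + its force field."""
    return make_toy_crystal(8, 2, seed=1)


@pytest.fixture()
def toy_warm(toy):
    """Toy crystal with 300 K Maxwell velocities (fresh copy per test)."""
    system, ff = toy
    system = system.copy()
    system.velocities = make_velocity_ensemble(300.0, system.masses, seed=2)
    return system, ff


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
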