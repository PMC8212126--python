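import numpy as np
import pytest

from saxstool.fixtures import (
    NoiseSpec,
    SyntheticSystemSpec,
    default_q_grid,
    make_atom_cluster,
    make_two_domain_system,
    simulate_profile,
    to_rigid_system,
)


@pytest.fixture(scope="session")
def q_grid():
    return default_q_grid(80)


@pytest.fixture(scope="session")
def two_domain():
    """Toy two-domain bead molecule with a 6-bead linker."""
    return make_two_domain_system(SyntheticSystemSpec(seed=0))


@pytest.fixture(scope="session")
def two_domain_nolinker():
    return make_two_domain_system(SyntheticSystemSpec(linker_length=0, seed=0))


@pytest.fixture(scope="session")
def dock_target(two_domain_nolinker, q_grid):
    """Noisy profile generated from the two-domain system at its true pose."""
    return simulate_profile(two_domain_nolinker, q_grid, noise=NoiseSpec(seed=11))


@pytest.fixture(scope="session")
def atom_cluster():
    """Dense 150-atom globule with buried and surface atoms."""
    return make_atom_cluster(150, 11.0, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
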