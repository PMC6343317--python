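import numpy as np
import pytest

import morphomod as mm
from morphomod.datatypes import LandmarkDataset


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic study: 12 tips, all 16 regions, default structure."""
    return mm.simulate_study(mm.SimConfig(n_tips=12, seed=11))


@pytest.fixture(scope="session")
def small_aligned(small_sim):
    return mm.superimpose(small_sim.dataset, small_sim.region_map)


@pytest.fixture(scope="session")
def tree35():
    return mm.simulate_tree(35, seed=7)


def random_dataset(rng, n=5, p=7):
    coords = rng.standard_normal((n, p, 3)) * 3 + 10
    return LandmarkDataset(
        specimen_ids=[f"s{i}" for i in range(n)],
        point_ids=[f"p{j}" for j in range(p)],
        coords=coords,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
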