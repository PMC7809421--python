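import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from hemilat.atlas import default_atlas
from hemilat.simulate import SimulationConfig


@pytest.fixture(scope="session")
def atlas64():
    return default_atlas(32)


@pytest.fixture()
def tiny_config():
    """Small cohort whose hemisphere graphs still carry triangles
    (16 nodes at the default density gives a k=4 lattice)."""
    return SimulationConfig(
        n_preterm=6, n_term=5, nodes_per_hemisphere=16, seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
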