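import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from vifc import make_chain_mesh, make_icosphere
from vifc.surface_io import SurfaceMesh


@pytest.fixture(scope="session")
def ico0():
    return make_icosphere(0, 75.0)


@pytest.fixture(scope="session")
def ico2():
    return make_icosphere(2, 75.0)


@pytest.fixture(scope="session")
def ico2_small():
    """162 vertices at ~10 mm spacing so the full 14-56 mm grid is active."""
    return make_icosphere(2, 40.0)


@pytest.fixture(scope="session")
def ico3():
    return make_icosphere(3, 75.0)


@pytest.fixture(scope="session")
def chain10():
    return make_chain_mesh(10, spacing_mm=4.0)


@pytest.fixture
def tetra():
    coords = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    faces = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    return SurfaceMesh(coords, faces)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
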