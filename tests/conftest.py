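import numpy as np
import pytest

import paleowalk as pw


@pytest.fixture(scope="session")
def geometry64():
    return pw.GridGeometry(64, 64, cell_size=2.0)


@pytest.fixture(scope="session")
def dem64(geometry64):
    return pw.generate_dem(geometry64, seed=1)


@pytest.fixture(scope="session")
def climate64(geometry64):
    return pw.generate_climate(geometry64, n_slices=5, seed=2)


@pytest.fixture(scope="session")
def state64(dem64, climate64):
    return pw.make_state(dem64, climate64.precipitation[0], float(climate64.sea_level[0]), 75.0)


@pytest.fixture(scope="session")
def corridor():
    return pw.two_corridor_world()


@pytest.fixture(scope="session")
def corridor_map(corridor):
    return pw.ResistanceMap(corridor.geometry, corridor.cost)


@pytest.fixture(scope="session")
def uniform_torus():
    """Zero-resistance 64x64 world used with wrap=True for calibration runs."""
    g = pw.GridGeometry(64, 64, cell_size=1.0)
    return g, pw.ResistanceMap(g, np.zeros((64, 64)))


def flat_ramp(n=8, cell=1.0, drop=10.0, base=100.0):
    """Inclined plane: z decreases by ``drop`` m per column (east-draining)."""
    g = pw.GridGeometry(n, n, cell_size=cell)
    z = base + drop * (n - 1 - np.arange(n))[None, :] * np.ones((n, 1))
    return pw.ElevationGrid(g, z)
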