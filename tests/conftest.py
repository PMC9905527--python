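import numpy as np
import pytest

from hexeco.grid import GridSpec, ISEA3HGrid


@pytest.fixture(scope="session")
def grid() -> ISEA3HGrid:
    """One shared grid with the default orientation."""
    return ISEA3HGrid(GridSpec())


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20230207)


def random_sphere_points(rng, n):
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    lat = np.degrees(np.arcsin(np.clip(u[:, 2], -1, 1)))
    lon = np.degrees(np.arctan2(u[:, 1], u[:, 0]))
    return u, lat, lon
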