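import numpy as np
import pytest

from sarcgeo import SceneSpec, build_thick_filament
from sarcgeo.crowns import CylinderModel


@pytest.fixture(scope="session")
def default_spec():
    return SceneSpec(seed=0)


@pytest.fixture(scope="session")
def single_filament(default_spec):
    """One noise-free ground-truth thick filament (93 crowns)."""
    return build_thick_filament(default_spec)


@pytest.fixture(scope="session")
def z_axis_cylinder():
    return CylinderModel(np.zeros(3), np.array([0.0, 0.0, 1.0]))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rigid_transform(rng):
    """A uniformly random rotation matrix and a translation vector."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.normal(scale=200.0, size=3)
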