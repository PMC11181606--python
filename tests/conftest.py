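import warnings

import numpy as np
import pytest

from pcltunnel.geometry import plateau_plane_from_mesh
from pcltunnel.synthetic import (
    PrismSpec,
    TibiaParams,
    generate_tibia,
    prism_tibia,
)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def default_tibia():
    """Default synthetic proximal tibia with its ground-truth landmarks."""
    return generate_tibia(TibiaParams())


@pytest.fixture(scope="session")
def default_plateau(default_tibia):
    mesh, lm = default_tibia
    return plateau_plane_from_mesh(mesh, lm.frame)


@pytest.fixture(scope="session")
def prism():
    """Analytic prism 'tibia' (mesh, landmarks, spec)."""
    spec = PrismSpec()
    mesh, lm = prism_tibia(spec)
    return mesh, lm, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(20240617)


def random_rigid_transform(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation + bounded translation as a 4x4 matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    m = np.eye(4)
    m[:3, :3] = rot
    m[:3, 3] = rng.uniform(-50, 50, 3)
    return m
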