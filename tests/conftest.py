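import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles importable

from brachyqa.source_model import DwellPoint, SourceModel
from brachyqa.synthetic_fixtures import FixtureSpec, make_phantom, make_ring_plan


@pytest.fixture(scope="session")
def toy_source():
    """Toy source with unit tables, Lambda = 1.1 cGy/(h U), L = 0.36 cm."""
    return SourceModel.toy(dose_rate_constant=1.1)


@pytest.fixture(scope="session")
def ir_source():
    """The packaged representative tabulated Ir-192 source."""
    return SourceModel.packaged("ir192-generic")


@pytest.fixture
def reference_dwell():
    """Unit-strength dwell at the origin pointing along +z, one hour."""
    return DwellPoint(position_mm=[0, 0, 0], direction=[0, 0, 1], time_s=3600.0,
                      air_kerma_strength_U=1.0, channel_id="ch1")


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=1, source_model="toy")


@pytest.fixture(scope="session")
def ring_plan(fixture_spec):
    return make_ring_plan(fixture_spec)


@pytest.fixture(scope="session")
def phantom(fixture_spec):
    return make_phantom(fixture_spec)


def circle_positions(n, radius=15.0, center=(0.0, 0.0, 10.0), normal=(0.0, 0.0, 1.0),
                     rng=None, sigma=0.0):
    """Dwell positions equally spaced CCW on a circle, optional Gaussian noise."""
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(normal)))] = 1.0
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    phi = 2 * np.pi * np.arange(n) / n
    pos = (np.asarray(center, float)[None]
           + radius * (np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * v))
    tangents = -np.sin(phi)[:, None] * u + np.cos(phi)[:, None] * v
    if sigma > 0:
        pos = pos + rng.normal(0, sigma, pos.shape)
    return pos, tangents
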