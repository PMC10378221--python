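import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from garuds.dynamics import random_unit_vectors
from garuds.geometry import BoxSpec, FlockState


@pytest.fixture
def box20() -> BoxSpec:
    return BoxSpec(np.full(3, 20.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230711)


def random_state(rng: np.random.Generator, n: int, box_edge: float = 20.0) -> FlockState:
    """A random flock spread over the whole box with valid speeds."""
    pos = rng.random((n, 3)) * box_edge
    vel = random_unit_vectors(rng, n) * rng.uniform(0.5, 1.0, n)[:, None]
    return FlockState(pos, vel)


@pytest.fixture
def random_state_factory(rng):
    return lambda n, box_edge=20.0: random_state(rng, n, box_edge)
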