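import numpy as np
import pytest

from pitchreflex import (
    STUDY1,
    SwarmConfig,
    TimeGrid,
    build_perturbation,
    get_model,
)


@pytest.fixture
def study1_grid() -> TimeGrid:
    return STUDY1.parse_grid


@pytest.fixture
def step_down(study1_grid):
    """A -100 cent step at onset on the standard parse grid."""
    return build_perturbation(study1_grid, -100.0, 0.0, 0.0)


@pytest.fixture
def ramp_down(study1_grid):
    """The gradual-onset profile: -100 cents over a 110 ms linear ramp."""
    return build_perturbation(study1_grid, -100.0, 110.0, 0.0)


@pytest.fixture
def d1():
    return get_model("D1")


@pytest.fixture
def tiny_swarm():
    """Small, fast swarm for unit tests of the fitting machinery."""
    return SwarmConfig(n_particles=400, patience=20, n_repeats=2, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
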