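import numpy as np
import pytest
from hypothesis import settings

import ductsim as d

# deterministic hypothesis runs everywhere
settings.register_profile("det", derandomize=True, deadline=None, max_examples=40)
settings.load_profile("det")


@pytest.fixture
def calib_params() -> d.ModelParams:
    """Transition probabilities of the no-exposure calibration narrative."""
    return d.ModelParams(p_mut=0.021, p_die=0.495, p_spr=0.009)


@pytest.fixture
def weak_model() -> d.CellModel:
    """Two-state demo, weak interaction (internal 0.05, spreading 0.01)."""
    return d.reduce_two_state(0.05, 0.01)


@pytest.fixture
def strong_model() -> d.CellModel:
    """Two-state demo, strong interaction (internal 0.01, spreading 0.05)."""
    return d.reduce_two_state(0.01, 0.05)


@pytest.fixture
def torus_20() -> d.Lattice:
    return d.Lattice(circumference=20, n_rings=20, wrap_axial=True)


def random_params(rng: np.random.Generator, with_spreading: bool = False) -> d.ModelParams:
    p_mut = rng.uniform(0.0, 0.5)
    p_die = rng.uniform(0.0, 1.0 - p_mut)
    p_spr = rng.uniform(0.0, 0.05) if with_spreading else 0.0
    return d.ModelParams(p_mut, p_die, p_spr)
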