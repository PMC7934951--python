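import numpy as np
import pytest

from msm.config import control_config
from msm.engine import Simulation
from msm.lattice import VegfField
from msm.mesh import fresh_vessel


@pytest.fixture(scope="session")
def control_vessel():
    """Default 10-cell control vessel (shared read-only geometry)."""
    return fresh_vessel(10, VegfField(mode="gradient", V=0.04))


@pytest.fixture()
def two_cell_sim():
    cfg = control_config(**{"vessel.n_cells": 2})
    return Simulation(cfg, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
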