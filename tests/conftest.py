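"""Shared fixtures: small and default synthetic embryos, rendered once per session."""
import numpy as np
import pytest

import smadgrad as sg
from smadgrad.config import RunConfig


@pytest.fixture(scope="session")
def default_geometry():
    return sg.EmbryoGeometry()


@pytest.fixture(scope="session")
def small_geometry():
    """A compact embryo for fast unit tests (same shape regime, ~1/3 scale)."""
    return sg.EmbryoGeometry(sphere_radius_um=100.0, shell_thickness_um=25.0,
                             nucleus_radius_um=4.0, n_nuclei=250)


@pytest.fixture(scope="session")
def default_stack_seed1():
    """Default noisy synthetic embryo, seed 1 (shared across tests)."""
    return sg.simulate_embryo(seed=1)


@pytest.fixture(scope="session")
def noiseless_stack_seed1():
    return sg.simulate_embryo(seed=1, noise=None)


@pytest.fixture(scope="session")
def small_stack(small_geometry):
    return sg.simulate_embryo(geometry=small_geometry, seed=3,
                              z_halfdepth_um=16.0)


@pytest.fixture(scope="session")
def ratio_config():
    return RunConfig(analysis={"normalization": "nuclear_ratio"})
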