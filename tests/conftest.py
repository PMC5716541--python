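"""Shared fixtures: reference mesh, protocol, Jacobian and GN model.

Session scope keeps the expensive artifacts (1600-element mesh, its
Jacobian and reconstruction matrix) shared across test modules.
"""

import numpy as np
import pytest

from eitpost.forward import compute_jacobian, solve_forward
from eitpost.inverse import build_reconstruction_matrix
from eitpost.mesh import build_circular_mesh
from eitpost.protocol import adjacent_protocol

BACKGROUND = 0.9  # S/m, saline at 20 C


@pytest.fixture(scope="session")
def protocol16():
    return adjacent_protocol(16)


@pytest.fixture(scope="session")
def ref_mesh():
    return build_circular_mesh(1600, 16)


@pytest.fixture(scope="session")
def small_mesh():
    """~200-element mesh for finite-difference comparisons."""
    return build_circular_mesh(196, 16)


@pytest.fixture(scope="session")
def ref_sigma(ref_mesh):
    return np.full(ref_mesh.n_elements, BACKGROUND)


@pytest.fixture(scope="session")
def ref_solution(ref_mesh, ref_sigma, protocol16):
    return solve_forward(ref_mesh, ref_sigma, protocol16)


@pytest.fixture(scope="session")
def ref_jacobian(ref_mesh, ref_sigma, protocol16):
    return compute_jacobian(ref_mesh, ref_sigma, protocol16)


@pytest.fixture(scope="session")
def gn_model(ref_jacobian):
    return build_reconstruction_matrix(ref_jacobian)
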