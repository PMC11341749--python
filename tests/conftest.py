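"""Shared fixtures: parameter sets and coarse solved stenosis cases.

PDE solves are expensive, so flow/tensor solutions on coarse grids are
session-scoped and shared across test modules.
"""

import numpy as np
import pytest

from vwfflow.core import VWFParams
from vwfflow.flow import solve_flow
from vwfflow.geometry import MeshSpec, StenosisGeometry, build_mesh
from vwfflow.transport import solve_vwf_field

COARSE = dict(dz_fine=0.12, dz_far=0.6, n_radial=33)


@pytest.fixture(scope="session")
def table1_params() -> VWFParams:
    """Published dimensional VWF parameter set (L = 22.6)."""
    return VWFParams()


@pytest.fixture(scope="session")
def straight_pipe_flow():
    """Poiseuille solution of the solver on a straight pipe at Re = 400."""
    mesh = build_mesh(StenosisGeometry(h=0.0), MeshSpec(**COARSE))
    return solve_flow(mesh, 400.0)


@pytest.fixture(scope="session")
def coarse_stenosis_flow():
    """Coarse-grid 50% stenosis flow at Re = 400 (l1=1.5, l2=2)."""
    mesh = build_mesh(StenosisGeometry(h=0.5, l1=1.5, l2=2.0), MeshSpec(**COARSE))
    return solve_flow(mesh, 400.0)


@pytest.fixture(scope="session")
def coarse_stenosis_tensors(coarse_stenosis_flow, table1_params):
    return solve_vwf_field(coarse_stenosis_flow, table1_params)


@pytest.fixture(scope="session")
def coarse_shallow_flow():
    """Coarse-grid shallow-ramp stenosis (l2=5) flow at Re = 400."""
    mesh = build_mesh(StenosisGeometry(h=0.5, l1=1.5, l2=5.0), MeshSpec(**COARSE))
    return solve_flow(mesh, 400.0)


@pytest.fixture(scope="session")
def coarse_shallow_tensors(coarse_shallow_flow, table1_params):
    return solve_vwf_field(coarse_shallow_flow, table1_params)


@pytest.fixture
def rng():
    return np.random.default_rng(20240409)
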