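"""Shared fixtures.

The FEM fixtures run on deliberately coarse, convergence-checked meshes so
the whole suite stays within an ordinary CI budget; the solver itself is
mesh-agnostic and the acceptance sweep uses a finer discretization.
"""

from __future__ import annotations

import numpy as np
import pytest

from cathmech.data import (FITTED_C01, FITTED_C10, FITTED_C11, FITTED_D,
                           reported_summary)
from cathmech.fit import FitParams
from cathmech.geometry import ModelGeometry
from cathmech.material import MaterialParams
from cathmech.mesh import MeshSpec, build_mesh
from cathmech.pipeline import FemForwardModel
from cathmech.solver import ContactSimulation, SolverSettings

CF_LEVELS = [10, 15, 20, 25, 30, 40, 50, 60, 70, 80]


@pytest.fixture(scope="session")
def geom():
    return ModelGeometry()


@pytest.fixture(scope="session")
def fitted_material():
    return MaterialParams(FITTED_C10, FITTED_C01, FITTED_C11)


@pytest.fixture(scope="session")
def fitted_params():
    return FitParams(FITTED_C10, FITTED_C01, FITTED_C11, FITTED_D)


@pytest.fixture(scope="session")
def coarse_spec():
    """~500-element mesh: fast unit-test discretization."""
    return MeshSpec(min_edge_at_tip=0.15, max_edge_far_field=8.0, growth=1.5)


@pytest.fixture(scope="session")
def sweep_spec():
    """~800-element mesh used for the acceptance sweep: its insertion
    depths agree with the next refinement level to ~0.1 mm."""
    return MeshSpec(min_edge_at_tip=0.08, max_edge_far_field=8.0, growth=1.35)


@pytest.fixture(scope="session")
def coarse_mesh(geom, coarse_spec):
    return build_mesh(geom, coarse_spec)


@pytest.fixture(scope="session")
def fixture_table():
    return reported_summary(provenance=False)


@pytest.fixture(scope="session")
def fitted_sweep(geom, fitted_material, sweep_spec):
    """Full CF sweep at the reported parameter set; shared by acceptance,
    equilibrium, monotonicity and surface-metric tests."""
    mesh = build_mesh(geom, sweep_spec)
    sim = ContactSimulation(geom, fitted_material, mesh)
    sim.apply_precompression(FITTED_D, 3)
    states = {}
    sim.load_to_force(CF_LEVELS[0], 4)
    states[CF_LEVELS[0]] = sim.state()
    for cf in CF_LEVELS[1:]:
        sim.load_to_force(cf, 2)
        states[cf] = sim.state()
    return states


@pytest.fixture(scope="session")
def tiny_forward(geom):
    """Cheapest usable forward model, for the inverse-fit recovery test."""
    return FemForwardModel(
        geom=geom,
        mesh_spec=MeshSpec(min_edge_at_tip=0.2, max_edge_far_field=10.0,
                           growth=1.6),
        phase1_steps=2, phase2_steps_first=3, phase2_steps=1)
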