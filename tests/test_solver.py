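"""Contact-solver verification: oracles, invariants, determinism."""

import numpy as np
import pytest

import cathmech.material as mat_mod
from cathmech.geometry import GRAMS_TO_NEWTON, LoadProtocol, ModelGeometry
from cathmech.material import MaterialParams
from cathmech.mesh import MeshSpec, build_mesh
from cathmech.solver import (ContactSimulation, SolverSettings,
                             mesh_convergence_study, solve_contact)

from conftest import CF_LEVELS


def test_unloaded_problem_stays_at_rest(geom, fitted_material, coarse_mesh):
    state = solve_contact(coarse_mesh, fitted_material, geom,
                          LoadProtocol(D=0.0, cf_grams=0.0))
    assert state.converged
    assert state.electrode_tip_depth == 0.0
    assert np.allclose(state.nodal_displacements, 0.0)
    assert np.allclose(state.surface_profile[:, 1], 0.0)


def test_element_kernel_matches_reference_material(geom, fitted_material,
                                                   coarse_mesh):
    """The solver's closed-form axisymmetric Piola kernel must agree with
    the general batched constitutive routine to round-off."""
    sim = ContactSimulation(geom, fitted_material, coarse_mesh)
    rng = np.random.default_rng(1)
    u = 1e-7 * rng.standard_normal(2 * coarse_mesh.n_nodes)
    F11, F12, F21, F22, F33, J = sim._deformation(sim._gather(u))
    P = sim._piola_components(F11, F12, F21, F22, F33, J)
    F = np.zeros(F11.shape + (3, 3))
    F[..., 0, 0], F[..., 0, 1] = F11, F12
    F[..., 1, 0], F[..., 1, 1] = F21, F22
    F[..., 2, 2] = F33
    S = mat_mod.second_piola(F, fitted_material)
    P_ref = np.einsum("...ij,...jk->...ik", F, S)
    for comp, (i, j) in zip(P, [(0, 0), (0, 1), (1, 0), (1, 1), (2, 2)]):
        scale = max(np.abs(P_ref[..., i, j]).max(), 1e-30)
        assert np.abs(comp - P_ref[..., i, j]).max() <= 1e-12 * scale


def test_internal_force_is_energy_gradient(geom, fitted_material,
                                           coarse_mesh):
    sim = ContactSimulation(geom, fitted_material, coarse_mesh)
    rng = np.random.default_rng(2)
    ndof = 2 * coarse_mesh.n_nodes
    u = 1e-7 * rng.standard_normal(ndof)
    f = sim._internal(u)
    K = sim._internal_tangent(u)
    d = 1e-12 * rng.standard_normal(ndof)
    f2 = sim._internal(u + d)
    assert np.linalg.norm(f2 - f - K @ d) <= 1e-6 * np.linalg.norm(f2 - f)


def test_small_load_matches_flat_punch_closed_form():
    """Rigid flat punch on an elastic half-space: depth within 5% of
    delta = F (1 - nu^2) / (2 a E) at CF = 0.1 g, no pre-compression,
    minimal fillet."""
    mat = MaterialParams(1271.0, 1156.0, 1501.0)
    geom = ModelGeometry(fillet_radius=2.33 / 2 / 50)
    spec = MeshSpec(min_edge_at_tip=0.06, max_edge_far_field=8.0, growth=1.35)
    sim = ContactSimulation(geom, mat, build_mesh(geom, spec))
    sim.load_to_force(0.1, 2)
    a = geom.electrode_radius * 1e-3
    F = 0.1 * GRAMS_TO_NEWTON
    delta = F * (1 - mat.nu ** 2) / (2 * a * mat.youngs_modulus)
    assert -sim.z_e == pytest.approx(delta, rel=0.05)


class TestFittedSweepInvariants:
    """Physical invariants on the full CF sweep at the fitted parameters."""

    def test_equilibrium_reaction_matches_applied_force(self, fitted_sweep):
        for cf, state in fitted_sweep.items():
            F = cf * GRAMS_TO_NEWTON
            assert state.converged
            assert state.contact_reaction_force == pytest.approx(F, rel=0.01)

    def test_insertion_depth_monotone_in_force(self, fitted_sweep):
        ids = [fitted_sweep[cf].electrode_tip_depth for cf in CF_LEVELS]
        assert all(b >= a for a, b in zip(ids, ids[1:]))

    def test_near_incompressibility(self, fitted_sweep):
        # volume-averaged |J - 1| < 3% even at the deepest indentation
        dev = fitted_sweep[80].diagnostics["volume_avg_J_dev"]
        assert dev < 0.03

    def test_penetration_within_penalty_tolerance(self, fitted_sweep):
        for state in fitted_sweep.values():
            pen = state.diagnostics["max_penetration_m"]
            assert pen < state.diagnostics["min_edge_m"] / 10

    def test_surface_profile_radii_increase(self, fitted_sweep):
        prof = fitted_sweep[80].surface_profile
        assert np.all(np.diff(prof[:, 0]) > -1e-9)

    def test_no_tissue_above_plate_beyond_hole(self, fitted_sweep, geom):
        prof = fitted_sweep[80].surface_profile
        outside = prof[:, 0] > geom.plate_hole_radius + 0.2
        pen_limit = fitted_sweep[80].diagnostics["min_edge_m"] / 10 / 1e-3
        assert np.all(prof[outside, 1] <= pen_limit)


def test_deterministic_resolve(geom, fitted_material, coarse_mesh):
    """Identical inputs must give bit-identical outputs."""
    def run():
        sim = ContactSimulation(geom, fitted_material, coarse_mesh)
        sim.apply_precompression(1.19, 2)
        sim.load_to_force(10.0, 3)
        return sim.u.copy()

    u1, u2 = run(), run()
    assert np.array_equal(u1, u2)


def test_convergence_study_single_level_informative(geom, fitted_material,
                                                    coarse_spec):
    study = mesh_convergence_study(geom, coarse_spec, fitted_material,
                                   LoadProtocol(D=1.19, cf_grams=20.0,
                                                n_load_steps_phase1=3,
                                                n_load_steps_phase2=5),
                                   n_levels=1)
    assert study.converged is None
    assert len(study.levels) == 1
    assert study.levels[0][1] > 0.0


def test_invalid_settings_rejected():
    with pytest.raises(ValueError):
        SolverSettings(newton_tol=-1.0)
    with pytest.raises(ValueError):
        SolverSettings(contact_penalty=0.0)
    with pytest.raises(ValueError):
        LoadProtocol(D=-1.0)
    with pytest.raises(ValueError):
        LoadProtocol(ramp_split=1.5)
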