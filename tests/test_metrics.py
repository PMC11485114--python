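"""Insertion-depth and surface-diameter measurement checks."""

import numpy as np
import pytest

from cathmech.geometry import GRAMS_TO_NEWTON, LoadProtocol
from cathmech.metrics import (DeformationMetrics, NotConvergedError, measure,
                              measure_id, measure_sd)
from cathmech.solver import ContactSimulation, DeformedState, solve_contact


def _dummy_state(profile, depth=1.0, converged=True):
    return DeformedState(nodal_displacements=np.zeros((1, 2)),
                         surface_profile=np.asarray(profile, dtype=float),
                         electrode_tip_depth=depth,
                         contact_reaction_force=0.1, applied_force=0.1,
                         converged=converged)


class TestMeasureOnSyntheticProfiles:
    def test_zero_load_state(self, geom, fitted_material, coarse_mesh):
        state = solve_contact(coarse_mesh, fitted_material, geom,
                              LoadProtocol())
        assert measure_id(state, geom) == 0.0
        with pytest.warns(UserWarning, match="never detaches"):
            assert measure_sd(state, geom) == 0.0

    def test_outermost_crossing_wins(self, geom):
        # re-contact island between two detached regions must be ignored
        prof = [(0.0, -3.0), (2.0, -1.0), (3.0, -0.01), (4.0, -1.0),
                (5.0, -0.05), (6.0, -0.0), (8.0, 0.0)]
        sd = measure_sd(_dummy_state(prof), geom, detach_tol=0.05)
        assert sd == pytest.approx(2 * 5.0, abs=1e-9)

    def test_crossing_is_interpolated(self, geom):
        prof = [(0.0, -1.0), (4.0, -0.1), (6.0, 0.0)]
        # linear profile crosses -0.05 at r = 5.0
        sd = measure_sd(_dummy_state(prof), geom, detach_tol=0.05)
        assert sd == pytest.approx(10.0)

    def test_id_ignores_detach_tol(self, geom):
        st = _dummy_state([(0.0, -1.0), (6.0, 0.0)], depth=2.34)
        for tol in (0.01, 0.05, 0.5):
            m = measure(st, geom, tol)
            assert m.id_mm == 2.34

    def test_nonconverged_state_refused(self, geom):
        st = _dummy_state([(0.0, -1.0)], converged=False)
        with pytest.raises(NotConvergedError):
            measure_id(st, geom)
        with pytest.raises(NotConvergedError):
            measure_sd(st, geom)

    def test_invalid_tolerance_rejected(self, geom):
        with pytest.raises(ValueError):
            measure_sd(_dummy_state([(0.0, -1.0)]), geom, detach_tol=0.0)


class TestMetricsInvariants:
    def test_sd_is_twice_detachment_radius(self):
        m = DeformationMetrics(cf=20.0, id_mm=1.0, sd_mm=6.0,
                               detachment_radius_mm=3.0)
        assert m.sd_mm == 2 * m.detachment_radius_mm
        with pytest.raises(ValueError):
            DeformationMetrics(cf=20.0, id_mm=1.0, sd_mm=6.0,
                               detachment_radius_mm=2.0)

    def test_negative_measures_rejected(self):
        with pytest.raises(ValueError):
            DeformationMetrics(cf=20.0, id_mm=-1.0, sd_mm=0.0,
                               detachment_radius_mm=0.0)


class TestOnFittedSweep:
    def test_sd_monotone_in_force(self, fitted_sweep, geom):
        from conftest import CF_LEVELS

        sds = [measure_sd(fitted_sweep[cf], geom) for cf in CF_LEVELS]
        assert all(b >= a - 1e-6 for a, b in zip(sds, sds[1:]))

    def test_sd_exceeds_electrode_diameter_under_load(self, fitted_sweep,
                                                      geom):
        sd = measure_sd(fitted_sweep[10], geom)
        assert sd > 2 * geom.electrode_radius

    def test_sd_stable_under_tolerance_halving(self, fitted_sweep, geom):
        state = fitted_sweep[80]
        sd1 = measure_sd(state, geom, 0.05)
        sd2 = measure_sd(state, geom, 0.025)
        prof = state.surface_profile
        i = np.searchsorted(prof[:, 0], sd1 / 2)
        local_spacing = prof[min(i + 1, len(prof) - 1), 0] - prof[i - 1, 0]
        assert abs(sd2 - sd1) <= 2 * local_spacing

    def test_reported_cf_matches_level(self, fitted_sweep, geom):
        m = measure(fitted_sweep[40], geom)
        assert m.cf == pytest.approx(40.0)
        assert m.converged


def test_force_displacement_mode_duality(geom, fitted_material, coarse_mesh):
    """Force-controlled depth at CF* must be recovered as the reaction of a
    displacement-controlled solve at that depth (within 1%)."""
    sim_f = ContactSimulation(geom, fitted_material, coarse_mesh)
    sim_f.apply_precompression(1.19, 2)
    sim_f.load_to_force(20.0, 4)
    depth = -sim_f.z_e * 1e3

    sim_d = ContactSimulation(geom, fitted_material, coarse_mesh)
    sim_d.apply_precompression(1.19, 2)
    reaction = sim_d.indent_to_depth(depth)
    assert reaction == pytest.approx(20.0 * GRAMS_TO_NEWTON, rel=0.01)
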