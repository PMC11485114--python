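"""Mooney-Rivlin energy, stress and parameter-mapping checks."""

import numpy as np
import pytest

from cathmech.material import (InvalidKinematicsError, KinematicState,
                               MaterialParams, d_from_params, second_piola,
                               strain_energy, strain_energy_density, stress)

FITTED = MaterialParams(1271.0, 1156.0, 1501.0)


def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _random_near_incompressible_F(rng, scale=0.1):
    F = np.eye(3) + scale * rng.standard_normal((3, 3))
    F *= np.linalg.det(F) ** (-1 / 3) * (1 + 1e-3 * rng.standard_normal())
    if np.linalg.det(F) <= 0:
        F = -F
    return F


class TestStrainEnergy:
    def test_zero_at_reference(self):
        kin = KinematicState.from_deformation_gradient(np.eye(3))
        assert strain_energy(kin, FITTED) == pytest.approx(0.0, abs=1e-12)
        assert kin.J == pytest.approx(1.0)
        assert kin.I1bar == pytest.approx(3.0)
        assert kin.I2bar == pytest.approx(3.0)

    def test_incompressible_uniaxial_stretch_value(self):
        # lambda = 1.1 isochoric uniaxial stretch; scalar evaluation of the
        # energy gives ~67.5 Pa with the fitted constants
        lam = 1.1
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
        kin = KinematicState.from_deformation_gradient(F)
        assert kin.J == pytest.approx(1.0, abs=1e-12)
        W = strain_energy(kin, FITTED)
        assert W == pytest.approx(67.51, rel=1e-3)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(42)
        F = _random_near_incompressible_F(rng)
        W0 = strain_energy_density(F, FITTED)
        for _ in range(100):
            R = _random_rotation(rng)
            W = strain_energy_density(R @ F, FITTED)
            assert W == pytest.approx(W0, rel=1e-10)

    def test_negative_J_rejected(self):
        F = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(InvalidKinematicsError):
            strain_energy_density(F, FITTED)


class TestStress:
    def test_zero_at_reference(self):
        S = stress(KinematicState.from_deformation_gradient(np.eye(3)), FITTED)
        assert np.allclose(S, 0.0, atol=1e-9)

    def test_consistent_with_energy_gradient(self):
        # first Piola P = F S must equal dW/dF by central differences
        rng = np.random.default_rng(7)
        h = 1e-7
        for _ in range(100):
            F = _random_near_incompressible_F(rng, scale=0.05)
            S = second_piola(F, FITTED)
            P = F @ S
            P_fd = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    Fp, Fm = F.copy(), F.copy()
                    Fp[i, j] += h
                    Fm[i, j] -= h
                    P_fd[i, j] = (strain_energy_density(Fp, FITTED)
                                  - strain_energy_density(Fm, FITTED)) / (2 * h)
            assert np.linalg.norm(P - P_fd) <= 1e-5 * np.linalg.norm(P_fd)

    @pytest.mark.parametrize("gamma", [1e-4, 5e-5])
    def test_small_strain_shear_modulus(self, gamma):
        # simple shear probe: sigma_12 / gamma -> mu = 2 (c10 + c01)
        F = np.eye(3)
        F[0, 1] = gamma
        S = second_piola(F, FITTED)
        sigma = (F @ S @ F.T) / np.linalg.det(F)
        mu = sigma[0, 1] / gamma
        assert mu == pytest.approx(FITTED.shear_modulus, rel=0.01)

    def test_small_strain_bulk_modulus(self):
        # pure dilatation F = (1+e) I leaves the isochoric invariants
        # untouched, so W = (J-1)^2/d with J-1 ~ 3e; the second difference
        # (W+ - 2 W0 + W-)/e^2 = 18/d, i.e. bulk modulus K = 2/d
        eps = 1e-4
        W = [float(strain_energy_density((1 + s * eps) * np.eye(3), FITTED))
             for s in (-1, 0, 1)]
        K_probe = (W[0] - 2 * W[1] + W[2]) / (9 * eps ** 2)
        assert K_probe == pytest.approx(FITTED.bulk_modulus, rel=0.01)


class TestParameterMapping:
    def test_d_from_fitted_constants(self):
        d = d_from_params(1271.0, 1156.0, 0.49)
        assert d == pytest.approx(0.02 / 2427.0, rel=1e-12)
        assert d == pytest.approx(8.24e-6, rel=1e-3)

    def test_incompressible_limit(self):
        assert d_from_params(1000.0, 0.0, 0.4999999) < 1e-9

    def test_halves_when_moduli_double(self):
        assert d_from_params(2 * 1271.0, 2 * 1156.0, 0.49) == pytest.approx(
            0.5 * d_from_params(1271.0, 1156.0, 0.49))

    @pytest.mark.parametrize("nu", [0.5, 0.6, 0.0, -0.1])
    def test_invalid_poisson_rejected(self, nu):
        with pytest.raises(ValueError):
            d_from_params(1000.0, 500.0, nu)

    @pytest.mark.parametrize("kwargs", [
        dict(c10=-1.0, c01=0.0), dict(c10=0.0, c01=1.0),
        dict(c10=1.0, c01=-1.0), dict(c10=1.0, c01=1.0, c11=-1.0),
        dict(c10=1.0, c01=1.0, nu=0.55),
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MaterialParams(**kwargs)

    def test_d_is_derived_not_free(self):
        p = MaterialParams(1271.0, 1156.0, 1501.0)
        assert p.d == d_from_params(p.c10, p.c01, p.nu)
        with pytest.raises(Exception):
            MaterialParams(1271.0, 1156.0, 1501.0, d=1e-6)  # no such field
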