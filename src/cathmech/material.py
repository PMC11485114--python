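"""Three-parameter Mooney-Rivlin hyperelasticity for passive myocardium.

The strain-energy density is expressed in the isochoric (unimodular)
invariants of the right Cauchy-Green tensor ``C = F^T F``::

    W = c10 (I1b - 3) + c01 (I2b - 3) + c11 (I1b - 3)(I2b - 3) + (J - 1)^2 / d

where ``I1b = J^(-2/3) tr(C)``, ``I2b = J^(-4/3) I2(C)`` and ``J = det F``.
The volumetric penalty coefficient ``d`` is not an independent constant: it
is tied to ``c10``, ``c01`` and the Poisson ratio through the usual
material-card convention ``d = (1 - 2 nu) / (c10 + c01)``, so near
incompressibility (``nu = 0.49``) enters as a stiff quadratic penalty on
volume change.  (The alternative convention that enforces exact consistency
of the initial bulk modulus with a chosen kappa, ``d = 2 / kappa``, is the
same formula up to the identification ``kappa = 2 (c10 + c01) / (1 - 2 nu)
= 2 / d``; only the route to ``d`` differs, not the energy.)

All tensor routines are batched: they accept deformation gradients of shape
``(..., 3, 3)`` and return correspondingly shaped results.  They are also
dtype-agnostic so that complex-step differentiation can be driven through
them by the FEM assembly.

Units: the Mooney-Rivlin constants are interpreted in Pa.  This makes the
small-strain shear modulus ``2 (c10 + c01)`` of the fitted myocardium card
about 4.9 kPa, the expected order for passive ventricular muscle; any other
SI reading would be off by orders of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidKinematicsError",
    "MaterialParams",
    "KinematicState",
    "d_from_params",
    "strain_energy",
    "strain_energy_density",
    "stress",
    "second_piola",
    "cauchy_stress",
]


class InvalidKinematicsError(ValueError):
    """Raised for kinematic states with non-positive volume ratio J."""


def d_from_params(c10: float, c01: float, nu: float) -> float:
    """Volumetric penalty coefficient ``d`` (1/Pa) implied by the card.

    ``d = (1 - 2 nu) / (c10 + c01)``; the incompressible limit ``nu -> 0.5``
    sends ``d -> 0`` (infinite bulk stiffness), which is why ``nu`` must stay
    strictly below 0.5 in this displacement-based formulation.
    """
    if not 0.0 < nu < 0.5:
        raise ValueError(
            f"Poisson ratio must lie in (0, 0.5) for a finite penalty; got nu={nu}"
        )
    if c10 + c01 <= 0.0:
        raise ValueError("c10 + c01 must be positive")
    return (1.0 - 2.0 * nu) / (c10 + c01)


@dataclass(frozen=True)
class MaterialParams:
    """Mooney-Rivlin constants (Pa) plus Poisson ratio.

    ``d`` is always derived via :func:`d_from_params`; it is deliberately not
    a constructor argument so it can never drift out of sync with the free
    constants during fitting.
    """

    c10: float
    c01: float
    c11: float = 0.0
    nu: float = 0.49

    def __post_init__(self) -> None:
        if self.c10 <= 0.0:
            raise ValueError(f"c10 must be positive, got {self.c10}")
        if self.c01 < 0.0 or self.c11 < 0.0:
            raise ValueError("c01 and c11 must be non-negative")
        d_from_params(self.c10, self.c01, self.nu)  # validates nu

    @property
    def d(self) -> float:
        """Volumetric penalty coefficient (1/Pa)."""
        return d_from_params(self.c10, self.c01, self.nu)

    @property
    def shear_modulus(self) -> float:
        """Small-strain shear modulus mu = 2 (c10 + c01), Pa."""
        return 2.0 * (self.c10 + self.c01)

    @property
    def bulk_modulus(self) -> float:
        """Small-strain bulk modulus kappa = 2 / d, Pa."""
        return 2.0 / self.d

    @property
    def youngs_modulus(self) -> float:
        """Small-strain Young's modulus E = 2 mu (1 + nu), Pa."""
        return 2.0 * self.shear_modulus * (1.0 + self.nu)


def _invariants(F: np.ndarray):
    """Return (C, J, I1, I2) for batched deformation gradients."""
    C = np.einsum("...ji,...jk->...ik", F, F)
    J = np.linalg.det(F)
    I1 = np.trace(C, axis1=-2, axis2=-1)
    CC = np.einsum("...ij,...ji->...", C, C)
    I2 = 0.5 * (I1 * I1 - CC)
    return C, J, I1, I2


def _check_J(J: np.ndarray) -> None:
    if np.any(np.real(J) <= 0.0):
        raise InvalidKinematicsError("non-positive volume ratio J = det(F)")


@dataclass(frozen=True)
class KinematicState:
    """Pointwise kinematics: deformation gradient and derived invariants.

    For axisymmetric problems ``F`` carries the hoop stretch in its (3, 3)
    slot; the class itself is agnostic of any symmetry.
    """

    F: np.ndarray
    J: float = field(init=False)
    I1bar: float = field(init=False)
    I2bar: float = field(init=False)

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        if F.shape[-2:] != (3, 3):
            raise ValueError("F must have shape (..., 3, 3)")
        _, J, I1, I2 = _invariants(F)
        _check_J(J)
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "J", J)
        object.__setattr__(self, "I1bar", J ** (-2.0 / 3.0) * I1)
        object.__setattr__(self, "I2bar", J ** (-4.0 / 3.0) * I2)

    @classmethod
    def from_deformation_gradient(cls, F: np.ndarray) -> "KinematicState":
        return cls(F=np.asarray(F, dtype=float))


def strain_energy_density(F: np.ndarray, params: MaterialParams) -> np.ndarray:
    """W (Pa) for batched deformation gradients of shape (..., 3, 3)."""
    _, J, I1, I2 = _invariants(np.asarray(F))
    _check_J(J)
    I1b = J ** (-2.0 / 3.0) * I1
    I2b = J ** (-4.0 / 3.0) * I2
    return (
        params.c10 * (I1b - 3.0)
        + params.c01 * (I2b - 3.0)
        + params.c11 * (I1b - 3.0) * (I2b - 3.0)
        + (J - 1.0) ** 2 / params.d
    )


def strain_energy(kin: KinematicState, params: MaterialParams) -> float:
    """Strain-energy density (Pa) at a kinematic state."""
    return float(strain_energy_density(kin.F, params))


def second_piola(F: np.ndarray, params: MaterialParams) -> np.ndarray:
    """Second Piola-Kirchhoff stress S = 2 dW/dC, batched.

    Closed form from the invariant derivatives:

    dI1b/dC = J^(-2/3) (I - I1/3 C^-1)
    dI2b/dC = J^(-4/3) (I1 I - C - 2 I2/3 C^-1)
    dJ/dC   = J/2 C^-1
    """
    F = np.asarray(F)
    C, J, I1, I2 = _invariants(F)
    _check_J(J)
    Cinv = np.linalg.inv(C)
    I1b = J ** (-2.0 / 3.0) * I1
    I2b = J ** (-4.0 / 3.0) * I2
    W1 = params.c10 + params.c11 * (I2b - 3.0)  # dW/dI1b
    W2 = params.c01 + params.c11 * (I1b - 3.0)  # dW/dI2b

    eye = np.zeros_like(C)
    eye[..., 0, 0] = eye[..., 1, 1] = eye[..., 2, 2] = 1.0

    a = J[..., None, None]
    dI1b = a ** (-2.0 / 3.0) * (eye - (I1 / 3.0)[..., None, None] * Cinv)
    dI2b = a ** (-4.0 / 3.0) * (
        I1[..., None, None] * eye - C - (2.0 * I2 / 3.0)[..., None, None] * Cinv
    )
    dvol = (2.0 / params.d) * ((J - 1.0) * J)[..., None, None] * Cinv
    return 2.0 * (W1[..., None, None] * dI1b + W2[..., None, None] * dI2b) + dvol


def stress(kin: KinematicState, params: MaterialParams) -> np.ndarray:
    """Second Piola-Kirchhoff stress tensor (Pa) at a kinematic state.

    The second Piola-Kirchhoff measure is the natural work conjugate for the
    total-Lagrangian assembly used by the solver; push forward with
    :func:`cauchy_stress` when true stresses are wanted.
    """
    return second_piola(kin.F, params)


def cauchy_stress(F: np.ndarray, params: MaterialParams) -> np.ndarray:
    """Cauchy stress sigma = J^-1 F S F^T, batched."""
    F = np.asarray(F)
    S = second_piola(F, params)
    J = np.linalg.det(F)
    return (
        np.einsum("...ij,...jk,...lk->...il", F, S, F)
        / J[..., None, None]
    )
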