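"""Deformation outcome measures: insertion depth and surface diameter.

Insertion depth (ID) is the vertical distance from the undeformed
tissue-surface reference plane — the plate underside, which is also the
experimental height-gauge zero — down to the lowest point of the electrode
tip.  Surface diameter (SD) is the diameter of the region where the tissue
top surface has detached from the plate: twice the outermost radius at
which the deformed profile lies more than ``detach_tol`` below the plate
plane.  The tolerance stands in for the experimental "visually identified"
border of the deformed area and is deliberately exposed: the simulated
plate-tissue gap decays shallowly with radius, so SD depends strongly on
what gap one calls visible (see the methods note).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import GRAMS_TO_NEWTON, ModelGeometry
from .solver import DeformedState

__all__ = ["DeformationMetrics", "measure_id", "measure_sd", "measure"]

DEFAULT_DETACH_TOL = 0.05  # mm


class NotConvergedError(RuntimeError):
    """Raised when metrics are requested from a non-converged state."""


@dataclass(frozen=True)
class DeformationMetrics:
    """One CF level's simulated outcomes (mm / grams-force)."""

    cf: float
    id_mm: float
    sd_mm: float
    detachment_radius_mm: float
    converged: bool = True

    def __post_init__(self) -> None:
        if self.id_mm < 0.0 or self.sd_mm < 0.0:
            raise ValueError("depth and diameter must be non-negative")
        if abs(self.sd_mm - 2.0 * self.detachment_radius_mm) > 1e-9:
            raise ValueError("sd_mm must equal twice the detachment radius")


def _require_converged(state: DeformedState) -> None:
    if not state.converged:
        raise NotConvergedError(
            "state did not converge (reaction "
            f"{state.contact_reaction_force:.4g} N vs applied "
            f"{state.applied_force:.4g} N); metrics would be meaningless")


def measure_id(state: DeformedState, geom: ModelGeometry) -> float:
    """Insertion depth (mm): plate-underside plane to electrode tip apex."""
    _require_converged(state)
    return float(state.electrode_tip_depth)


def measure_sd(state: DeformedState, geom: ModelGeometry,
               detach_tol: float = DEFAULT_DETACH_TOL) -> float:
    """Surface diameter (mm) of the detached area at gap ``detach_tol``.

    Scans the deformed top-surface profile from the outside in and returns
    twice the outermost radius where the gap below the plate plane first
    exceeds ``detach_tol`` (linear interpolation between surface nodes);
    interior re-contact islands are ignored by construction.  Returns 0
    with a warning when the surface never detaches that far.
    """
    _require_converged(state)
    if detach_tol <= 0.0:
        raise ValueError("detach_tol must be positive")
    prof = np.asarray(state.surface_profile)
    below = prof[:, 1] < -detach_tol
    idx = np.flatnonzero(below)
    if idx.size == 0:
        warnings.warn("surface never detaches beyond detach_tol; SD = 0",
                      stacklevel=2)
        return 0.0
    i = idx[-1]  # outermost detached node
    if i + 1 >= prof.shape[0]:
        return float(2.0 * prof[i, 0])
    r0, z0 = prof[i]
    r1, z1 = prof[i + 1]
    if z1 == z0:
        r_cross = r0
    else:
        r_cross = r0 + (-detach_tol - z0) / (z1 - z0) * (r1 - r0)
    return float(2.0 * r_cross)


def measure(state: DeformedState, geom: ModelGeometry,
            detach_tol: float = DEFAULT_DETACH_TOL) -> DeformationMetrics:
    """Bundle ID and SD for one converged state."""
    sd = measure_sd(state, geom, detach_tol)
    return DeformationMetrics(
        cf=state.applied_force / GRAMS_TO_NEWTON,
        id_mm=measure_id(state, geom),
        sd_mm=sd,
        detachment_radius_mm=sd / 2.0,
        converged=state.converged,
    )
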