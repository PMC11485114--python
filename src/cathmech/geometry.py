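"""Model geometry and load protocol for the catheter-on-tissue problem.

The scene is axisymmetric about the catheter axis: a cylindrical tissue
block (default 80 mm radius x 40 mm high) whose top surface rests against a
rigid transparent plate, with a rigid stainless-steel electrode (2.33 mm
diameter cylinder, blunt tip filleted at 1/8 of its radius) descending
through a clearance hole in the plate.  The electrode and plate are eleven
orders of magnitude stiffer than myocardium, so both are represented as
analytic rigid frictionless obstacles rather than meshed elastic bodies.

All lengths at this interface are millimetres; the solver converts to SI
internally.
"""

from __future__ import annotations

from dataclasses import dataclass

GRAMS_TO_NEWTON = 9.80665e-3
"""Weight of one gram-force in newtons."""


@dataclass(frozen=True)
class ModelGeometry:
    """Axisymmetric scene dimensions (mm)."""

    electrode_radius: float = 2.33 / 2.0
    electrode_length: float = 10.0
    fillet_radius: float | None = None  # default: electrode_radius / 8
    plate_thickness: float = 1.0
    plate_clearance: float = 0.05
    plate_hole_radius: float | None = None  # default: electrode_radius + clearance
    tissue_radius: float = 80.0
    tissue_height: float = 40.0

    def __post_init__(self) -> None:
        if self.fillet_radius is None:
            object.__setattr__(self, "fillet_radius", self.electrode_radius / 8.0)
        if self.plate_hole_radius is None:
            object.__setattr__(
                self, "plate_hole_radius", self.electrode_radius + self.plate_clearance
            )
        if not 0.0 < self.fillet_radius < self.electrode_radius:
            raise ValueError("fillet radius must lie in (0, electrode_radius)")
        if self.plate_hole_radius < self.electrode_radius:
            raise ValueError("plate hole must admit the electrode")
        if self.tissue_radius <= 4.0 * self.electrode_radius:
            raise ValueError("tissue radius must dwarf the electrode radius")
        if min(self.tissue_height, self.plate_thickness, self.electrode_length) <= 0.0:
            raise ValueError("all lengths must be positive")


@dataclass(frozen=True)
class LoadProtocol:
    """Two-phase quasi-static load schedule.

    Phase 1 (pseudo-time 0 to ``ramp_split``): the bottom of the tissue is
    displaced upward from 0 to ``D`` mm against the fixed plate, providing
    the pre-compression that flattens the surface.  Phase 2 (``ramp_split``
    to 1): the electrode is loaded from 0 to the weight of ``cf_grams``
    while ``D`` is held.  The ramps are load-step fractions of a unit
    pseudo-time; the analysis is static, so only the step counts matter.
    """

    D: float = 0.0  # mm
    cf_grams: float = 0.0
    ramp_split: float = 0.1
    n_load_steps_phase1: int = 5
    n_load_steps_phase2: int = 10

    def __post_init__(self) -> None:
        if self.D < 0.0 or self.cf_grams < 0.0:
            raise ValueError("D and cf_grams must be non-negative")
        if not 0.0 < self.ramp_split < 1.0:
            raise ValueError("ramp_split must lie in (0, 1)")
        if min(self.n_load_steps_phase1, self.n_load_steps_phase2) < 1:
            raise ValueError("step counts must be at least 1")

    @property
    def cf_newton(self) -> float:
        """Contact force in newtons."""
        return self.cf_grams * GRAMS_TO_NEWTON
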