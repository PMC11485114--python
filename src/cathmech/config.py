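"""Structured configuration for the pipeline (YAML, strict schema).

Units at the configuration boundary follow the experimental reporting
convention: contact force in grams-force, lengths in mm, moduli in Pa.
Unknown keys are rejected so typos fail loudly instead of silently
reverting to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fit import FitOptions, FitParams
from .geometry import LoadProtocol, ModelGeometry
from .mesh import MeshSpec
from .solver import SolverSettings

__all__ = ["PipelineConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class PipelineConfig:
    geometry: ModelGeometry = field(default_factory=ModelGeometry)
    material: dict = field(default_factory=lambda: dict(
        c10=1271.0, c01=1156.0, c11=1501.0, nu=0.49))
    load: LoadProtocol = field(default_factory=LoadProtocol)
    mesh: MeshSpec = field(default_factory=MeshSpec)
    solver: SolverSettings = field(default_factory=SolverSettings)
    fit: FitOptions = field(default_factory=FitOptions)
    detach_tol: float = 0.05  # mm, SD visibility threshold
    seed: int = 0
    output_dir: str = "."

    def fit_params(self) -> FitParams:
        m = self.material
        return FitParams(c10=m["c10"], c01=m["c01"], c11=m.get("c11", 0.0),
                         D=self.load.D)


def _build(cls, block: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown keys in '{name}' block: {sorted(unknown)}")
    return cls(**block)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> PipelineConfig:
    """Read a YAML config; missing blocks fall back to defaults."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        raw = {**raw, **overrides}
    known = {"geometry", "material", "load", "mesh", "solver", "fit",
             "detach_tol", "seed", "output_dir"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")

    material = dict(c10=1271.0, c01=1156.0, c11=1501.0, nu=0.49)
    mat_block = raw.get("material", {})
    unknown = set(mat_block) - set(material) - {"d"}
    if unknown:
        raise ValueError(f"unknown keys in 'material' block: {sorted(unknown)}")
    if "d" in mat_block:
        raise ValueError(
            "the volumetric coefficient d is derived from (c10, c01, nu) "
            "and cannot be set directly")
    material.update(mat_block)

    return PipelineConfig(
        geometry=_build(ModelGeometry, raw.get("geometry", {}), "geometry"),
        material=material,
        load=_build(LoadProtocol, raw.get("load", {}), "load"),
        mesh=_build(MeshSpec, raw.get("mesh", {}), "mesh"),
        solver=_build(SolverSettings, raw.get("solver", {}), "solver"),
        fit=_build(FitOptions, raw.get("fit", {}), "fit"),
        detach_tol=float(raw.get("detach_tol", 0.05)),
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", ".")),
    )


def config_hash(cfg: PipelineConfig) -> str:
    """Stable digest of a config, for provenance records."""
    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        raise TypeError(str(type(o)))

    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=enc)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
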