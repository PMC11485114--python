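"""Minimal legacy-VTK (ASCII) export of the mesh and displacement field.

The legacy VTK format is a simple self-describing text format understood by
ParaView and friends; quadratic triangles map to VTK cell type 22. Writing
it directly keeps visual inspection possible without a mesh-I/O
dependency.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .mesh import Mesh

__all__ = ["write_vtk"]


def write_vtk(path: str | Path, mesh: Mesh,
              displacements_mm: np.ndarray | None = None) -> None:
    """Write the reference mesh (and optionally the displacement field, mm)
    as an unstructured grid."""
    nodes = mesh.nodes / 1e-3  # mm for inspection
    tris = mesh.tris
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("axisymmetric tissue half-section (r, z in mm)\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(nodes)} double\n")
        for r, z in nodes:
            fh.write(f"{r:.9g} {z:.9g} 0\n")
        fh.write(f"CELLS {len(tris)} {7 * len(tris)}\n")
        for t in tris:
            # VTK quadratic triangle: corners then midside (same ordering)
            fh.write("6 " + " ".join(map(str, t)) + "\n")
        fh.write(f"CELL_TYPES {len(tris)}\n")
        fh.write("22\n" * len(tris))
        if displacements_mm is not None:
            fh.write(f"POINT_DATA {len(nodes)}\n")
            fh.write("VECTORS displacement double\n")
            for ur, uz in np.asarray(displacements_mm):
                fh.write(f"{ur:.9g} {uz:.9g} 0\n")
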