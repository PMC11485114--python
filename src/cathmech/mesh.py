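"""Graded axisymmetric meshing of the tissue half-section.

Only the tissue is meshed: the electrode and plate act as analytic rigid
obstacles (see :mod:`cathmech.solver`).  The half-section ``[0, R] x [-H, 0]``
is covered by a logically rectangular grid whose spacing grows geometrically
from the electrode-tip contact zone (default 27 um) to the far field
(default 2.4 mm).  A transfinite blend relaxes the fine surface/axis spacing
toward a uniform grid with depth and radius, so the far-field elements stay
well shaped instead of degenerating into high-aspect slivers as a pure
tensor-product grading would.  Each (possibly warped) quad is split into two
straight-sided 6-node triangles; the quadratic field on an affine triangle
is the standard remedy for volumetric locking at nu = 0.49.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import ModelGeometry

MM = 1e-3  # mm -> m

__all__ = ["MeshSpec", "Mesh", "build_mesh"]


@dataclass(frozen=True)
class MeshSpec:
    """Mesh sizing (mm unless noted).

    ``growth`` is the geometric edge-growth ratio away from the tip; if
    ``target_element_count`` is given, ``growth`` is adjusted by bisection to
    approach that triangle count instead.
    """

    min_edge_at_tip: float = 0.027
    max_edge_far_field: float = 2.4
    element_order: int = 2
    growth: float = 1.08
    target_element_count: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.min_edge_at_tip < self.max_edge_far_field:
            raise ValueError("need 0 < min_edge_at_tip < max_edge_far_field")
        if self.element_order != 2:
            raise ValueError("only quadratic (6-node) triangles are supported")
        if not 1.005 < self.growth < 2.5:
            raise ValueError("growth ratio must lie in (1.005, 2.5)")

    def refined(self, factor: float = 2.0) -> "MeshSpec":
        """Spec with all edge targets shrunk by ``factor`` (for convergence
        studies); any element-count target is dropped."""
        return replace(
            self,
            min_edge_at_tip=self.min_edge_at_tip / factor,
            max_edge_far_field=self.max_edge_far_field / factor,
            target_element_count=None,
        )


@dataclass(frozen=True)
class Mesh:
    """Quadratic triangle mesh of the tissue half-section (SI units, m).

    ``tris[:, :3]`` are the corner vertices (counter-clockwise),
    ``tris[:, 3:]`` the midside nodes opposite to edges (0-1, 1-2, 2-0).
    """

    nodes: np.ndarray  # (n_nodes, 2): (r, z), metres
    tris: np.ndarray  # (n_elements, 6)
    top_nodes: np.ndarray  # node ids with z = 0, sorted by r
    bottom_nodes: np.ndarray  # node ids with z = -H
    axis_nodes: np.ndarray  # node ids with r = 0

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tris.shape[0]

    def edge_lengths(self) -> np.ndarray:
        """Unique corner-edge lengths (m)."""
        v = self.tris[:, :3]
        e = np.concatenate([v[:, [0, 1]], v[:, [1, 2]], v[:, [2, 0]]])
        e = np.unique(np.sort(e, axis=1), axis=0)
        d = self.nodes[e[:, 0]] - self.nodes[e[:, 1]]
        return np.hypot(d[:, 0], d[:, 1])

    def min_edge_near_tip(self, radius_m: float = 5e-4) -> float:
        """Shortest corner edge with both ends within ``radius_m`` of the
        tip contact point (origin)."""
        v = self.tris[:, :3]
        e = np.concatenate([v[:, [0, 1]], v[:, [1, 2]], v[:, [2, 0]]])
        rr = np.hypot(self.nodes[:, 0], self.nodes[:, 1])
        keep = (rr[e[:, 0]] <= radius_m) & (rr[e[:, 1]] <= radius_m)
        d = self.nodes[e[keep, 0]] - self.nodes[e[keep, 1]]
        return float(np.min(np.hypot(d[:, 0], d[:, 1])))

    def min_angle_deg(self) -> float:
        """Smallest interior corner angle over all triangles (degrees)."""
        p = self.nodes[self.tris[:, :3]]  # (n, 3, 2)
        angles = []
        for k in range(3):
            a = p[:, (k + 1) % 3] - p[:, k]
            b = p[:, (k + 2) % 3] - p[:, k]
            cosang = np.einsum("ij,ij->i", a, b) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
            )
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        return float(np.min(angles))


def _graded_points(length: float, h0: float, growth: float, hmax: float) -> np.ndarray:
    """1-D point set on [0, length]: spacing h0 at 0, geometric growth capped
    at hmax, final point rescaled to land exactly on ``length``."""
    pts = [0.0]
    h = h0
    while pts[-1] < length:
        pts.append(pts[-1] + h)
        h = min(h * growth, hmax)
    pts = np.asarray(pts)
    pts *= length / pts[-1]  # overshoot => factor <= 1, min edge only shrinks
    pts[-1] = length
    return pts


def _grid_counts(geom: ModelGeometry, spec: MeshSpec) -> tuple[np.ndarray, np.ndarray]:
    r_f = _graded_points(geom.tissue_radius, spec.min_edge_at_tip, spec.growth,
                         spec.max_edge_far_field)
    z_f = _graded_points(geom.tissue_height, spec.min_edge_at_tip, spec.growth,
                         spec.max_edge_far_field)
    return r_f, z_f


def build_mesh(geom: ModelGeometry, spec: MeshSpec | None = None) -> Mesh:
    """Build the graded quadratic-triangle mesh of the tissue half-section."""
    spec = spec or MeshSpec()
    if spec.target_element_count is not None:
        spec = _spec_for_count(geom, spec)

    r_fine, z_fine = _grid_counts(geom, spec)
    n_r, n_z = len(r_fine) - 1, len(z_fine) - 1
    r_coarse = np.linspace(0.0, geom.tissue_radius, n_r + 1)
    z_coarse = np.linspace(0.0, geom.tissue_height, n_z + 1)

    # Transfinite blend: fine near the tip, ~uniform far away in both axes.
    w = (z_fine / geom.tissue_height)[None, :]  # relax r-grading with depth
    v = (r_fine / geom.tissue_radius)[:, None]  # relax z-grading with radius
    rr = r_fine[:, None] * (1.0 - w) + r_coarse[:, None] * w
    zz = -(z_fine[None, :] * (1.0 - v) + z_coarse[None, :] * v)

    nv = (n_r + 1) * (n_z + 1)
    verts = np.empty((nv, 2))
    vid = np.arange(nv).reshape(n_r + 1, n_z + 1)
    verts[:, 0] = (rr * MM).ravel()
    verts[:, 1] = (zz * MM).ravel()

    corner_tris = []
    for i in range(n_r):
        for j in range(n_z):
            a, b = vid[i, j], vid[i + 1, j]
            c, d = vid[i + 1, j + 1], vid[i, j + 1]
            if (i + j) % 2 == 0:
                cand = [(a, b, c), (a, c, d)]
            else:
                cand = [(a, b, d), (b, c, d)]
            corner_tris.extend(cand)
    corner = np.asarray(corner_tris)

    # Enforce counter-clockwise orientation (positive area).
    p = verts[corner]
    area2 = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 2, 0] - p[:, 0, 0]
    ) * (p[:, 1, 1] - p[:, 0, 1])
    flip = area2 < 0
    corner[flip] = corner[flip][:, [0, 2, 1]]
    if np.any(np.abs(area2) <= 0.0):
        raise RuntimeError("degenerate element produced by grading; adjust MeshSpec")

    # Midside nodes (quadratic field on affine triangles).
    nodes = [verts]
    edge_mid: dict[tuple[int, int], int] = {}
    next_id = nv
    mids = np.empty((corner.shape[0], 3), dtype=int)
    new_pts = []
    for t, (i0, i1, i2) in enumerate(corner):
        for k, (u_, v_) in enumerate(((i0, i1), (i1, i2), (i2, i0))):
            key = (u_, v_) if u_ < v_ else (v_, u_)
            idx = edge_mid.get(key)
            if idx is None:
                idx = next_id
                edge_mid[key] = idx
                new_pts.append(0.5 * (verts[u_] + verts[v_]))
                next_id += 1
            mids[t, k] = idx
    nodes.append(np.asarray(new_pts))
    all_nodes = np.vstack(nodes)
    tris = np.hstack([corner, mids])

    H = geom.tissue_height * MM
    top = np.where(np.abs(all_nodes[:, 1]) < 1e-12)[0]
    top = top[np.argsort(all_nodes[top, 0])]
    bottom = np.where(np.abs(all_nodes[:, 1] + H) < 1e-9 * max(H, 1.0))[0]
    axis = np.where(np.abs(all_nodes[:, 0]) < 1e-12)[0]
    return Mesh(nodes=all_nodes, tris=tris, top_nodes=top,
                bottom_nodes=bottom, axis_nodes=axis)


def _count_for_growth(geom: ModelGeometry, spec: MeshSpec, growth: float) -> int:
    r_f, z_f = _grid_counts(geom, replace(spec, growth=growth,
                                          target_element_count=None))
    return 2 * (len(r_f) - 1) * (len(z_f) - 1)


def _spec_for_count(geom: ModelGeometry, spec: MeshSpec) -> MeshSpec:
    """Bisection on the growth ratio toward ``target_element_count``
    (count decreases monotonically with growth)."""
    target = spec.target_element_count
    lo, hi = 1.01, 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _count_for_growth(geom, spec, mid) > target:
            lo = mid
        else:
            hi = mid
    best = min((lo, hi, 0.5 * (lo + hi)),
               key=lambda g: abs(_count_for_growth(geom, spec, g) - target))
    return replace(spec, growth=best, target_element_count=None)
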