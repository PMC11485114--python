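"""End-to-end orchestration: forward CF sweeps and validation reports.

A forward sweep solves the contact problem at an ascending list of contact
forces on one persistent simulation, so each level warm-starts from the
previous equilibrium — both faster and closer to the experiment, where the
force was increased monotonically at each site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import data as data_mod
from . import metrics as metrics_mod
from .fit import FitParams, mse_id, mse_sd
from .geometry import ModelGeometry
from .mesh import MeshSpec
from .regression import linear_fit
from .solver import ContactSimulation, SolveError, SolverSettings

log = logging.getLogger("cathmech")

__all__ = ["FemForwardModel", "run_forward_sweep", "run_validation_report"]


@dataclass
class FemForwardModel:
    """Callable handle ``(FitParams, cf_levels) -> DataFrame`` used by the
    inverse fit and the pipeline.

    ``mesh_spec`` controls fidelity/cost: the inverse fit runs dozens of
    forward sweeps, so it is usually driven on a coarser, convergence-
    checked mesh than a one-off validation sweep.
    """

    geom: ModelGeometry = None
    mesh_spec: MeshSpec = None
    settings: SolverSettings = None
    detach_tol: float = metrics_mod.DEFAULT_DETACH_TOL
    phase1_steps: int = 5
    phase2_steps_first: int = 4
    phase2_steps: int = 2
    nu: float = 0.49
    keep_states: bool = False

    def __post_init__(self) -> None:
        self.geom = self.geom or ModelGeometry()
        self.mesh_spec = self.mesh_spec or MeshSpec()
        self.settings = self.settings or SolverSettings()
        self._mesh_cache = None
        self.states: dict = {}

    def _mesh(self):
        from .mesh import build_mesh

        if self._mesh_cache is None:
            self._mesh_cache = build_mesh(self.geom, self.mesh_spec)
        return self._mesh_cache

    def __call__(self, params: FitParams, cf_levels) -> pd.DataFrame:
        cf_levels = sorted(float(c) for c in cf_levels)
        sim = ContactSimulation(self.geom, params.material(self.nu),
                                self._mesh(), self.settings)
        rows = []
        if params.D > 0.0:
            sim.apply_precompression(params.D, self.phase1_steps)
        first = True
        for cf in cf_levels:
            try:
                sim.load_to_force(cf, self.phase2_steps_first if first
                                  else self.phase2_steps)
            except SolveError as exc:
                raise SolveError(f"forward solve failed at CF={cf} g: {exc}"
                                 ) from exc
            first = False
            state = sim.state()
            if self.keep_states:
                self.states[cf] = state
            m = metrics_mod.measure(state, self.geom, self.detach_tol)
            rows.append(dict(cf_g=cf, id_mm=m.id_mm, sd_mm=m.sd_mm,
                             detachment_radius_mm=m.detachment_radius_mm,
                             converged=state.converged))
            log.info("CF=%5.1f g: ID=%6.3f mm  SD=%6.2f mm", cf, m.id_mm,
                     m.sd_mm)
        return pd.DataFrame(rows)


def run_forward_sweep(params: FitParams, cf_list,
                      forward: FemForwardModel | None = None) -> pd.DataFrame:
    """One DeformationMetrics row per CF (columns: cf_g, id_mm, sd_mm,
    detachment_radius_mm, converged).  An empty ``cf_list`` yields an empty
    table; duplicate CF entries yield duplicate identical rows."""
    forward = forward or FemForwardModel()
    cf_list = [float(c) for c in cf_list]
    if not cf_list:
        return pd.DataFrame(columns=["cf_g", "id_mm", "sd_mm",
                                     "detachment_radius_mm", "converged"])
    table = forward(params, sorted(set(cf_list)))
    table = table.set_index("cf_g").loc[cf_list].reset_index()
    return table


def run_forward_sweep_simple(params, cf_levels, detach_tol=0.05,
                             mesh_spec=None, settings=None) -> pd.DataFrame:
    """Convenience wrapper taking raw (c10, c01, c11, D)."""
    if not isinstance(params, FitParams):
        params = FitParams(*params)
    fm = FemForwardModel(mesh_spec=mesh_spec, settings=settings,
                         detach_tol=detach_tol)
    return run_forward_sweep(params, cf_levels, fm)


def run_validation_report(params: FitParams,
                          forward: FemForwardModel | None = None,
                          data: pd.DataFrame | None = None,
                          detach_tol_scan=(0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0),
                          ) -> dict:
    """Model-vs-experiment comparison bundle.

    Returns the forward table, MSE_ID / MSE_SD against the experiment
    summary, per-CF residuals, the CF-ID regression on the simulated curve,
    and a surface-diameter sensitivity scan over the detachment-visibility
    threshold (the experimental border was identified visually, so the
    threshold is the one genuinely uncertain post-processing choice).
    """
    forward = forward or FemForwardModel()
    forward.keep_states = True
    if data is None:
        data = data_mod.reported_summary(provenance=False)
    table = forward(params, data["cf_g"].tolist())
    pred = table.set_index("cf_g")

    def table_forward(p, cfs):
        return table  # reuse the solved sweep

    out: dict = {"forward_table": table}
    out["mse_id"] = mse_id(params, data, table_forward)
    usable = data.dropna(subset=["msd_mm", "msd_minor_mm"])
    out["mse_sd"] = mse_sd(params, usable, table_forward,
                           forward.detach_tol)
    out["per_cf_residuals_id"] = {
        float(c): float(pred.loc[float(c), "id_mm"] - m)
        for c, m in zip(data["cf_g"], data["id_mean_mm"])}
    fit_line = linear_fit(table["cf_g"], table["id_mm"])
    out["id_cf_regression"] = fit_line

    exp_sd = 0.5 * (usable["msd_mm"].to_numpy()
                    + usable["msd_minor_mm"].to_numpy())
    out["experimental_sd_mean"] = dict(zip(usable["cf_g"], exp_sd))

    # SD sensitivity to the visibility threshold: the experimental border
    # was identified by eye, so the gap one calls "detached" is the single
    # uncertain post-processing choice; the scan quantifies its leverage.
    scan = {}
    for tol in detach_tol_scan:
        sds, errs = {}, []
        for cf, sd_ref in zip(usable["cf_g"], exp_sd):
            st = forward.states.get(float(cf))
            if st is None:
                continue
            sd = metrics_mod.measure_sd(st, forward.geom, tol)
            sds[float(cf)] = sd
            errs.append((sd - sd_ref) ** 2)
        scan[tol] = dict(sd_mm=sds, mse=float(np.mean(errs)) if errs
                         else float("nan"))
    out["detach_tol_scan"] = scan
    return out
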