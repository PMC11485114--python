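"""Inverse identification of the material card from CF-ID data.

The forward FEM model maps (c10, c01, c11, D) to an insertion-depth curve
ID(CF).  The fit minimizes the mean-square error

    MSE = (1/N) sum_i (ID_comp(CF_i) - ID_exp(CF_i))^2     [mm^2]

over the experiment's CF levels by plain gradient descent with
Barzilai-Borwein (BB2, "short") step sizes.  Gradients are forward finite
differences of the objective — four extra forward sweeps per iteration —
computed on a scaled parameter space (log-transformed moduli, D normalized
by its initial value) that enforces positivity and balances magnitudes.
Only ID enters the objective; the surface diameter is a validation output.

Identifiability note: at small strains the response depends on c10 and c01
essentially through their sum 2(c10 + c01) (the shear modulus), so distinct
(c10, c01) splits produce nearly identical ID curves.  Recovery should be
judged on the predicted curve and on D, not on the individual constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .material import MaterialParams

__all__ = [
    "FitParams",
    "FitOptions",
    "FitResult",
    "mse_id",
    "mse_sd",
    "fit_parameters",
]


@dataclass(frozen=True)
class FitParams:
    """Free variables of the inverse problem: moduli (Pa) + pre-compression
    displacement D (mm)."""

    c10: float
    c01: float
    c11: float
    D: float

    def __post_init__(self) -> None:
        if self.c10 <= 0.0:
            raise ValueError("c10 must be positive")
        if self.c01 < 0.0 or self.c11 < 0.0:
            raise ValueError("c01 and c11 must be non-negative")
        if self.D < 0.0:
            raise ValueError("D must be non-negative")

    def material(self, nu: float = 0.49) -> MaterialParams:
        return MaterialParams(self.c10, self.c01, self.c11, nu=nu)


@dataclass(frozen=True)
class FitOptions:
    fd_rel_step: float = 5e-2  # relative FD step per scaled coordinate
    step_clip: tuple = (1e-4, 1e2)  # BB step bounds on the scaled space
    alpha0: float = 0.05  # first-step size: 5% move of the largest gradient
    tol_mse: float = 1e-3  # mm^2
    tol_grad: float = 1e-3
    max_iter: int = 50


@dataclass
class FitResult:
    params: FitParams
    mse_id: float
    mse_trajectory: list = field(default_factory=list)
    n_iterations: int = 0
    gradient_norm: float = float("nan")
    per_cf_residuals: dict = field(default_factory=dict)
    converged: bool = False
    stop_reason: str = ""


def _predict(forward, params: FitParams, cf_levels) -> pd.DataFrame:
    table = forward(params, list(cf_levels))
    missing = set(np.round(cf_levels, 6)) - set(np.round(table["cf_g"], 6))
    if missing:
        raise RuntimeError(f"forward model returned no rows for CF {sorted(missing)}")
    return table.set_index("cf_g")


def mse_id(params: FitParams, data: pd.DataFrame, forward) -> float:
    """Mean squared (simulated - experimental mean) insertion depth, mm^2.

    ``data`` rows: cf_g, id_mean_mm (the experiment-summary schema);
    ``forward`` is a callable (FitParams, cf_levels) -> DataFrame with
    columns cf_g, id_mm.
    """
    cf = data["cf_g"].to_numpy(dtype=float)
    table = _predict(forward, params, cf)
    resid = table.loc[cf, "id_mm"].to_numpy() - data["id_mean_mm"].to_numpy()
    return float(np.mean(resid ** 2))


def mse_sd(params: FitParams, data: pd.DataFrame, forward,
           detach_tol: float = 0.05) -> float:
    """Mean squared surface-diameter error over the measurable CF levels.

    Experimental reference per level is the mean of the major and minor
    diameters (the axisymmetric model produces a single diameter).  Rows
    without an MSD value (CF below the measurability limit) are skipped.
    """
    usable = data.dropna(subset=["msd_mm", "msd_minor_mm"])
    if usable.empty:
        raise ValueError("no CF level carries surface-diameter data")
    cf = usable["cf_g"].to_numpy(dtype=float)
    table = _predict(forward, params, cf)
    exp_sd = 0.5 * (usable["msd_mm"].to_numpy()
                    + usable["msd_minor_mm"].to_numpy())
    resid = table.loc[cf, "sd_mm"].to_numpy() - exp_sd
    return float(np.mean(resid ** 2))


def _to_scaled(p: FitParams, ref: FitParams) -> np.ndarray:
    return np.array([np.log(p.c10), np.log(max(p.c01, 1e-6)),
                     np.log(max(p.c11, 1e-6)), p.D / max(ref.D, 1e-6)])


def _from_scaled(x: np.ndarray, ref: FitParams) -> FitParams:
    return FitParams(c10=float(np.exp(x[0])), c01=float(np.exp(x[1])),
                     c11=float(np.exp(x[2])),
                     D=float(max(x[3], 0.05) * max(ref.D, 1e-6)))


def fit_parameters(data: pd.DataFrame, init: FitParams, forward,
                   options: FitOptions | None = None) -> FitResult:
    """Barzilai-Borwein gradient descent on the CF-ID mean-square error.

    Iterates x_{k+1} = x_k - alpha_k g_k on the scaled parameters with the
    BB2 step alpha_k = (dx . dg) / (dg . dg), clipped to ``step_clip``; the
    first step moves the steepest coordinate by ``alpha0`` (5%).  BB steps
    are deliberately non-monotone; the best-so-far iterate is tracked and
    returned.  Stops when the MSE change, the gradient norm, or the
    iteration budget is exhausted.  Forward failures during finite-
    difference probing are retried at half the probe step, then abort with
    the trajectory so far.
    """
    opt = options or FitOptions()
    cache: dict = {}

    def objective(x: np.ndarray) -> float:
        key = tuple(np.round(x, 12))
        if key not in cache:
            cache[key] = mse_id(_from_scaled(x, init), data, forward)
        return cache[key]

    def gradient(x: np.ndarray, f0: float) -> np.ndarray:
        g = np.empty_like(x)
        for i in range(x.size):
            # absolute step on the scaled space = relative perturbation of
            # the raw parameter (log-coordinates for the moduli)
            h = opt.fd_rel_step
            for attempt in range(2):
                xp = x.copy()
                xp[i] += h
                try:
                    g[i] = (objective(xp) - f0) / h
                    break
                except Exception:
                    if attempt == 1:
                        raise
                    h *= 0.5
        return g

    x = _to_scaled(init, init)
    traj: list = []
    best_x, best_f = x.copy(), np.inf
    x_prev = g_prev = None
    reason = "max_iter"
    n_done = 0
    g = np.zeros_like(x)

    for it in range(opt.max_iter):
        try:
            f = objective(x)
        except Exception as exc:
            reason = f"forward failure: {exc}"
            break
        traj.append(f)
        if f < best_f:
            best_f, best_x = f, x.copy()
        if f <= opt.tol_mse:
            reason = "mse_small"
            n_done = it + 1
            break
        try:
            g = gradient(x, f)
        except Exception as exc:
            reason = f"forward failure: {exc}"
            break
        gnorm = float(np.linalg.norm(g, np.inf))
        if gnorm < opt.tol_grad:
            reason = "gradient"
            n_done = it + 1
            break
        if (it >= 2 and abs(traj[-1] - traj[-2]) < opt.tol_mse
                and abs(traj[-2] - traj[-3]) < opt.tol_mse):
            reason = "mse_change"
            n_done = it + 1
            break
        if x_prev is None:
            alpha = opt.alpha0 / max(gnorm, 1e-12)
        else:
            dx = x - x_prev
            dg = g - g_prev
            denom = float(dg @ dg)
            alpha = float(dx @ dg) / denom if denom > 0 else opt.alpha0 / gnorm
            alpha = float(np.clip(alpha, *opt.step_clip))
        x_prev, g_prev = x.copy(), g.copy()
        x = x - alpha * g
        n_done = it + 1

    # final bookkeeping at the best iterate
    try:
        f_best = objective(best_x)
    except Exception:
        f_best = best_f
    params = _from_scaled(best_x, init)
    cf = data["cf_g"].to_numpy(dtype=float)
    per_cf: dict = {}
    try:
        table = _predict(forward, params, cf)
        per_cf = {float(c): float(table.loc[c, "id_mm"] - m)
                  for c, m in zip(cf, data["id_mean_mm"])}
    except Exception:
        pass
    return FitResult(params=params, mse_id=float(f_best),
                     mse_trajectory=traj, n_iterations=n_done,
                     gradient_norm=float(np.linalg.norm(g, np.inf)),
                     per_cf_residuals=per_cf,
                     converged=reason in ("gradient", "mse_change", "mse_small"),
                     stop_reason=reason)
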