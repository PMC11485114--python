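"""Simple-regression analysis of CF-deformation relationships.

Ordinary least squares of one outcome (ID, MSD or mSD, mm) on contact
force (grams-force), with the coefficient of determination and the
classical two-sided t-test on the slope.  Also provides the inverse map —
given an insertion depth, which contact force does the fitted line imply —
used to translate penetration depths reported by other groups (which did
not record CF) into equivalent contact forces, and the anisotropy ratio of
the elliptical experimental footprint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RegressionResult",
    "linear_fit",
    "cf_from_id",
    "anisotropy_ratio",
]


@dataclass(frozen=True)
class RegressionResult:
    slope: float  # outcome units per gram-force
    intercept: float  # outcome units
    r_squared: float
    p_value: float  # two-sided, H0: slope = 0; NaN for n < 3
    n: int

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def linear_fit(x, y) -> RegressionResult:
    """OLS fit y = slope * x + intercept.

    Requires n >= 2 and non-constant x; the slope p-value needs n >= 3
    (NaN otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if x.size < 2:
        raise ValueError("need at least two points")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate design: x is constant")
    res = stats.linregress(x, y)
    r2 = res.rvalue ** 2
    p = float(res.pvalue) if x.size >= 3 else float("nan")
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=float(r2), p_value=p, n=int(x.size))


def cf_from_id(id_mm: float, fit: RegressionResult,
               rounded: bool = True) -> float:
    """Invert the CF->ID line: contact force (g) giving depth ``id_mm``.

    ``rounded`` mirrors the integer-gram reporting convention.
    """
    if fit.slope == 0.0:
        raise ZeroDivisionError("zero slope: line is not invertible")
    cf = (id_mm - fit.intercept) / fit.slope
    return float(round(cf)) if rounded else float(cf)


def anisotropy_ratio(msd_minor: float, msd_major: float) -> float:
    """Minor/major surface-diameter ratio in percent (100 = circular)."""
    if msd_major <= 0.0:
        raise ValueError("major diameter must be positive")
    return 100.0 * msd_minor / msd_major
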