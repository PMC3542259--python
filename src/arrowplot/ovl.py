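"""Overlapping coefficient (OVL) of two kernel densities.

OVL = integral of min(f_X, f_Y) over the common support: 1 for identical
distributions and -> 0 for well separated ones.  The estimator works on the
two grid-evaluated kernel densities: it takes the pointwise minimum of the
densities on the union of both grids, adds the interpolated crossing (jump)
points where one density overtakes the other, sorts everything by abscissa,
and integrates with a trapezoidal rule on the resulting non-uniform grid.

Each density is evaluated off its own grid by linear interpolation and is
taken as zero outside its grid range (the grids already extend three
bandwidths past the data, where a Gaussian kernel is negligible).
"""

from __future__ import annotations

import numpy as np

from .kde import DensityEstimate, kde_grid

__all__ = [
    "min_envelope_points",
    "crossing_points",
    "trapezoid_nonuniform",
    "ovl",
    "ovl_from_densities",
]


def _eval_on(dens: DensityEstimate, x: np.ndarray) -> np.ndarray:
    """Linear interpolation of a density at ``x``, zero outside its grid."""
    return np.interp(x, dens.x, dens.y, left=0.0, right=0.0)


def min_envelope_points(densA: DensityEstimate, densB: DensityEstimate):
    """Pointwise minimum of two densities on the union of their grids.

    Returns
    -------
    (x, y) : pair of ndarrays
        Union-grid abscissas (ascending, unique) and min-density ordinates.
    """
    x = np.union1d(densA.x, densB.x)
    y = np.minimum(_eval_on(densA, x), _eval_on(densB, x))
    return x, y


def crossing_points(densA: DensityEstimate, densB: DensityEstimate):
    """Interpolated intersection points of two piecewise-linear densities.

    For each adjacent pair of union-grid abscissas across which
    ``sign(fA - fB)`` changes strictly, the crossing of the two local linear
    segments is returned.  Tangential contact (equality at a grid point with
    no sign change) is not a crossing, so points are never duplicated.

    Returns
    -------
    (x, y) : pair of ndarrays (possibly empty)
    """
    x = np.union1d(densA.x, densB.x)
    d = _eval_on(densA, x) - _eval_on(densB, x)
    s = np.sign(d)
    # strict sign change between adjacent points: product < 0
    idx = np.flatnonzero(s[:-1] * s[1:] < 0)
    if idx.size == 0:
        return np.empty(0), np.empty(0)
    x0, x1 = x[idx], x[idx + 1]
    d0, d1 = d[idx], d[idx + 1]
    t = d0 / (d0 - d1)
    xc = x0 + t * (x1 - x0)
    yA0 = _eval_on(densA, x0)
    yA1 = _eval_on(densA, x1)
    yc = yA0 + t * (yA1 - yA0)
    return xc, yc


def trapezoid_nonuniform(x, y) -> float:
    """Trapezoidal rule on a non-uniform grid: sum of 0.5*(y_i+y_{i+1})*dx_i."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points for trapezoidal integration")
    dx = np.diff(x)
    return float(np.sum(0.5 * (y[:-1] + y[1:]) * dx))


def _dedupe_min(x: np.ndarray, y: np.ndarray):
    """Sort by abscissa and resolve duplicate abscissas to the minimum ordinate."""
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    # group equal abscissas, keep min ordinate per group
    if x.size and np.any(np.diff(x) == 0):
        ux, inv = np.unique(x, return_inverse=True)
        uy = np.full(ux.size, np.inf)
        np.minimum.at(uy, inv, y)
        return ux, uy
    return x, y


def ovl_from_densities(densA: DensityEstimate, densB: DensityEstimate) -> float:
    """OVL of two grid-evaluated densities, clipped to [0, 1]."""
    xm, ym = min_envelope_points(densA, densB)
    xc, yc = crossing_points(densA, densB)
    x = np.concatenate([xm, xc])
    y = np.concatenate([ym, yc])
    x, y = _dedupe_min(x, y)
    area = trapezoid_nonuniform(x, y)
    return float(np.clip(area, 0.0, 1.0))


def ovl(
    sampleA,
    sampleB,
    n_grid: int = 512,
    cut: float = 3.0,
    bandwidth_rule: str = "adaptive",
) -> float:
    """Overlapping coefficient between the kernel densities of two samples.

    Parameters
    ----------
    sampleA, sampleB : array-like
        Two samples of (log-scale) expression values; each needs >= 2 finite
        values with nonzero spread.
    n_grid, cut, bandwidth_rule :
        Forwarded to :func:`arrowplot.kde.kde_grid`.

    Returns
    -------
    float in [0, 1]
    """
    dA = kde_grid(sampleA, n_grid=n_grid, cut=cut, bandwidth_rule=bandwidth_rule)
    dB = kde_grid(sampleB, n_grid=n_grid, cut=cut, bandwidth_rule=bandwidth_rule)
    return ovl_from_densities(dA, dB)
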