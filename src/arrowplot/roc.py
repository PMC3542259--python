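"""Nonparametric ROC machinery for two-group expression values.

The marker convention is fixed throughout the package: the *experimental*
group is the positive class and a value is called positive when it exceeds
the decision threshold, so up-regulated genes give AUC near 1 and
down-regulated genes AUC near 0.  The direction is never auto-flipped,
because curves that cross the chance diagonal ("not proper" ROC curves) are
themselves informative: they arise for genes with similar group means but
bimodal or unequal-variance distributions.

Provided here:

* ``auc_mw`` — the Mann-Whitney estimator of AUC = P(Y > X) + 0.5 P(Y = X);
* ``empirical_roc`` — the empirical ROC step curve, whose trapezoidal area
  equals ``auc_mw`` exactly (Bamber's identity);
* ``abcr`` — the area between the empirical ROC curve and the rising
  diagonal, summed over equal-width slices of the unit interval;
* ``tnrc`` — ABCR minus |AUC - 1/2|; large positive values flag curves that
  cross the diagonal (sigmoidal shape), i.e. candidate "special" genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = ["ROCCurve", "auc_mw", "empirical_roc", "abcr", "tnrc"]


@dataclass(frozen=True)
class ROCCurve:
    """An empirical ROC curve as paired (fpr, tpr) vertices.

    Both coordinate arrays are non-decreasing within [0, 1] and include the
    endpoints (0, 0) and (1, 1).
    """

    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        fpr = np.asarray(self.fpr, dtype=float)
        tpr = np.asarray(self.tpr, dtype=float)
        if fpr.shape != tpr.shape or fpr.ndim != 1 or fpr.size < 2:
            raise ValueError("fpr and tpr must be equal-length 1-D arrays")
        for name, a in (("fpr", fpr), ("tpr", tpr)):
            if np.any(np.diff(a) < 0) or a[0] != 0.0 or a[-1] != 1.0:
                raise ValueError(f"{name} must be non-decreasing from 0 to 1")
        object.__setattr__(self, "fpr", fpr)
        object.__setattr__(self, "tpr", tpr)

    @property
    def area(self) -> float:
        """Trapezoidal area under the curve (equals the Mann-Whitney AUC)."""
        return float(np.trapezoid(self.tpr, self.fpr))


def _validate_pair(control, experimental):
    x = np.asarray(control, dtype=float).ravel()
    y = np.asarray(experimental, dtype=float).ravel()
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    return x, y


def auc_mw(control, experimental) -> float:
    """Mann-Whitney estimate of AUC = P(Y > X), ties counted 1/2.

    Computed from midranks of the pooled sample, which is algebraically
    identical to averaging the pairwise kernel
    ``1[y > x] + 0.5 * 1[y == x]`` over all (x, y) pairs.
    """
    x, y = _validate_pair(control, experimental)
    ranks = rankdata(np.concatenate([x, y]), method="average")
    r_y = ranks[x.size :].sum()
    u = r_y - y.size * (y.size + 1) / 2.0
    return float(u / (x.size * y.size))


def empirical_roc(control, experimental) -> ROCCurve:
    """Empirical ROC curve with thresholds at every distinct pooled value.

    A sample value is classified positive when it is strictly greater than
    the threshold; sweeping the threshold down through the distinct pooled
    values traces the step curve from (0, 0) to (1, 1).
    """
    x, y = _validate_pair(control, experimental)
    thresholds = np.unique(np.concatenate([x, y]))[::-1]
    fpr = [0.0]
    tpr = [0.0]
    for c in thresholds:
        fpr.append(np.mean(x > c))
        tpr.append(np.mean(y > c))
    fpr.append(1.0)
    tpr.append(1.0)
    # threshold = pooled max duplicates the (0,0) vertex; drop duplicates
    pts = np.column_stack([fpr, tpr])
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(np.diff(pts, axis=0) != 0, axis=1)
    pts = pts[keep]
    return ROCCurve(fpr=pts[:, 0], tpr=pts[:, 1])


def _slice_areas(curve: ROCCurve, m0: int) -> np.ndarray:
    """Trapezoidal area of the ROC polyline within each of m0 equal-width
    slices of the FPR axis."""
    # insert the slice boundaries as vertices so each linear piece lies in
    # exactly one slice; vertical segments (dx = 0) carry no area
    bounds = np.linspace(0.0, 1.0, m0 + 1)
    fpr, tpr = curve.fpr, curve.tpr
    xs = [fpr]
    ys = [tpr]
    for b in bounds[1:-1]:
        i = np.searchsorted(fpr, b)
        if i < fpr.size and fpr[i] == b:
            continue  # already a vertex
        x0, x1 = fpr[i - 1], fpr[i]
        t = (b - x0) / (x1 - x0)
        xs.append(np.array([b]))
        ys.append(np.array([tpr[i - 1] + t * (tpr[i] - tpr[i - 1])]))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    order = np.lexsort((y, x))
    x, y = x[order], y[order]
    seg_area = 0.5 * (y[:-1] + y[1:]) * np.diff(x)
    mid = 0.5 * (x[:-1] + x[1:])
    which = np.clip(np.searchsorted(bounds, mid) - 1, 0, m0 - 1)
    areas = np.zeros(m0)
    np.add.at(areas, which, seg_area)
    return areas


def abcr(control, experimental) -> float:
    """Area between the empirical ROC curve and the rising diagonal.

    The unit FPR interval is divided into ``m0`` equal-width slices, where
    ``m0`` is the number of distinct pooled sample values (ties collapse).
    The statistic is the sum over slices of |partial ROC area - partial
    chance area|, the chance partial areas being (2k - 1) / (2 m0^2).  It is
    a distance between the two expression distributions: zero when the curve
    sits on the diagonal, and up to ~1/2 for complete separation.
    """
    x, y = _validate_pair(control, experimental)
    m0 = np.unique(np.concatenate([x, y])).size
    if m0 < 2:
        raise ValueError("need at least 2 distinct pooled values")
    curve = empirical_roc(x, y)
    auc_k = _slice_areas(curve, m0)
    k = np.arange(1, m0 + 1)
    a_k = (2 * k - 1) / (2.0 * m0 * m0)
    return float(np.abs(auc_k - a_k).sum())


def tnrc(control, experimental) -> float:
    """Test statistic for not-proper ROC curves: ABCR - |AUC - 1/2|.

    Near zero for curves entirely on one side of the diagonal; large
    positive values indicate a sigmoidal / crossing curve, the signature of
    equal-mean genes whose distributions differ in shape.
    """
    x, y = _validate_pair(control, experimental)
    return abcr(x, y) - abs(auc_mw(x, y) - 0.5)
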