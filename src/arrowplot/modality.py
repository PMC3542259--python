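"""Bimodality / multimodality detection from kernel density grid ordinates.

The detector reads the shape of an estimated density directly off its grid:
each grid point is marked "rising" when its ordinate is less than or equal to
the next one.  A unimodal density rises over a single contiguous run of grid
indices and then falls; if the rising indices split into two or more separated
runs, the density has at least two peaks and the verdict is multimodal.

No prominence threshold or extra smoothing is applied — the adaptive
bandwidth of the density estimate (min of s and IQR/1.34 spread) is what
keeps spurious noise peaks down.  Flat plateaus (consecutive equal ordinates)
count as rising, so a plateau never splits a run by itself.  Densities that
are multimodal only through sub-grid wiggles at machine precision are an
accepted blind spot of the rule.
"""

from __future__ import annotations

import numpy as np

from .kde import DensityEstimate, kde_grid

__all__ = ["is_multimodal", "modality_label", "MODALITY_LABELS"]

#: C = bimodal in control only, E = experimental only, B = both, U = neither.
MODALITY_LABELS = ("C", "E", "B", "U")


def is_multimodal(density) -> bool:
    """True if the grid ordinates show more than one rising run.

    Parameters
    ----------
    density : DensityEstimate or array-like
        A grid-evaluated density, or directly its ordinate sequence
        (at least 3 values).
    """
    if isinstance(density, DensityEstimate):
        y = density.y
    else:
        y = np.asarray(density, dtype=float).ravel()
    if y.size < 3:
        raise ValueError("need at least 3 grid ordinates")
    rising = np.flatnonzero(y[:-1] <= y[1:])
    if rising.size == 0:
        return False  # monotone decreasing: single (left-edge) mode
    return bool(np.any(np.diff(rising) != 1))


def modality_label(
    control,
    experimental,
    n_grid: int = 512,
    cut: float = 3.0,
    bandwidth_rule: str = "adaptive",
) -> str:
    """Which group(s) show a bimodal/multimodal kernel density.

    Returns one of ``"C"`` (control only), ``"E"`` (experimental only),
    ``"B"`` (both) or ``"U"`` (unimodal in both).  Group densities are
    estimated with the package's default kernel settings.
    """
    dc = kde_grid(control, n_grid=n_grid, cut=cut, bandwidth_rule=bandwidth_rule)
    de = kde_grid(experimental, n_grid=n_grid, cut=cut, bandwidth_rule=bandwidth_rule)
    return label_from_flags(is_multimodal(dc), is_multimodal(de))


def label_from_flags(control_multimodal: bool, experimental_multimodal: bool) -> str:
    """Combine the two per-group verdicts into a C/E/B/U label."""
    if control_multimodal and experimental_multimodal:
        return "B"
    if control_multimodal:
        return "C"
    if experimental_multimodal:
        return "E"
    return "U"
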