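"""The arrow-plot model: joint OVL/AUC gene statistics and selection.

The arrow plot ranks every gene of a two-group experiment by two
nonparametric statistics computed from the gene's control and experimental
expression vectors:

* **OVL** — the overlapping coefficient of the two kernel densities
  (1 = identical distributions, -> 0 = disjoint);
* **AUC** — the Mann-Whitney ROC area P(experimental > control), near 1 for
  up-regulation and near 0 for down-regulation.

Plotting OVL (abscissa) against AUC (ordinate) produces an arrow-shaped
cloud; genes are then selected by rectangular thresholds:

* UP:      AUC >= auc_up           and OVL < ovl_max
* DOWN:    AUC <= auc_down         and OVL < ovl_max
* SPECIAL: auc_special_low < AUC < auc_special_high and OVL < ovl_max,
  kept only if a kernel-density bimodality test fires in at least one group
  (step 2) — these are equal-mean genes whose distribution splits into
  sample subclasses, invisible to mean-based statistics.

Usage follows the model/results idiom::

    model = ArrowPlot(dataset)            # or ArrowPlot.from_dataframe(...)
    res = model.fit()                     # per-gene OVL and AUC
    sel = res.select()                    # adds label + modality columns
    print(res.summary())
    res.plot("arrow.png")
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import roc
from .datasets import ExpressionDataset
from .kde import DegenerateSampleError, kde_grid
from .modality import is_multimodal, label_from_flags
from .ovl import ovl_from_densities

__all__ = [
    "SelectionThresholds",
    "ArrowPlot",
    "ArrowPlotResults",
    "compute_gene_stats",
    "select_genes",
    "arrow_plot",
]

LABELS = ("UP", "DOWN", "SPECIAL", "NS", "UNDETERMINED")

#: plot colors: SPECIAL is colored by which group is bimodal
_COLORS = {
    "UP": "red",
    "DOWN": "blue",
    "SPECIAL/E": "orange",
    "SPECIAL/C": "cyan",
    "SPECIAL/B": "green",
    "NS": "0.7",
    "UNDETERMINED": "0.4",
}


@dataclass(frozen=True)
class SelectionThresholds:
    """Cutoffs of the rectangular selection regions in the (OVL, AUC) plane.

    Defaults reproduce the thresholds used for real two-channel microarray
    data (OVL < 0.5); :meth:`simulated` gives the stricter OVL < 0.3 preset
    used for the synthetic benchmark datasets.
    """

    auc_up: float = 0.9
    auc_down: float = 0.1
    auc_special_low: float = 0.4
    auc_special_high: float = 0.6
    ovl_max: float = 0.5

    def __post_init__(self) -> None:
        if not (
            0.0
            <= self.auc_down
            < self.auc_special_low
            < self.auc_special_high
            < self.auc_up
            <= 1.0
        ):
            raise ValueError(
                "need 0 <= auc_down < auc_special_low < auc_special_high "
                "<= auc_up <= 1"
            )
        if not 0.0 < self.ovl_max <= 1.0:
            raise ValueError("ovl_max must be in (0, 1]")

    @classmethod
    def lymphoma(cls) -> "SelectionThresholds":
        """OVL < 0.5 preset (real-data analysis)."""
        return cls(ovl_max=0.5)

    @classmethod
    def simulated(cls) -> "SelectionThresholds":
        """OVL < 0.3 preset (synthetic-data analysis)."""
        return cls(ovl_max=0.3)

    def replace(self, **kw) -> "SelectionThresholds":
        return replace(self, **kw)


def _gene_stats_row(x: np.ndarray, y: np.ndarray, n_grid: int, cut: float,
                    bandwidth_rule: str) -> dict:
    row = {
        "ovl": np.nan,
        "auc": np.nan,
        "n_control": int(x.size),
        "n_experimental": int(y.size),
        "status": "ok",
        "note": "",
    }
    try:
        if x.size < 2 or y.size < 2:
            raise DegenerateSampleError("fewer than 2 finite values in a group")
        dx = kde_grid(x, n_grid=n_grid, cut=cut, bandwidth_rule=bandwidth_rule)
        dy = kde_grid(y, n_grid=n_grid, cut=cut, bandwidth_rule=bandwidth_rule)
        row["ovl"] = ovl_from_densities(dx, dy)
        row["auc"] = roc.auc_mw(x, y)
    except (DegenerateSampleError, ValueError) as exc:
        row["status"] = "undetermined"
        row["note"] = str(exc)
    return row


def compute_gene_stats(
    dataset: ExpressionDataset,
    n_grid: int = 512,
    cut: float = 3.0,
    bandwidth_rule: str = "adaptive",
) -> pd.DataFrame:
    """Per-gene OVL and AUC for every gene of a dataset.

    Missing values are dropped per gene and group before estimation.  Genes
    that cannot be scored (a group constant or with fewer than two finite
    values) are reported with status ``undetermined`` instead of aborting.

    Returns
    -------
    DataFrame indexed by gene_id with columns
    ovl, auc, n_control, n_experimental, status, note.
    """
    ctrl = dataset.control.to_numpy(dtype=float)
    expr = dataset.experimental.to_numpy(dtype=float)
    rows = []
    for i in range(dataset.n_genes):
        x = ctrl[i][np.isfinite(ctrl[i])]
        y = expr[i][np.isfinite(expr[i])]
        rows.append(_gene_stats_row(x, y, n_grid, cut, bandwidth_rule))
    return pd.DataFrame(rows, index=dataset.gene_ids)


def select_genes(
    stats: pd.DataFrame,
    dataset: ExpressionDataset,
    thresholds: SelectionThresholds | None = None,
    n_grid: int = 512,
    cut: float = 3.0,
    bandwidth_rule: str = "adaptive",
) -> pd.DataFrame:
    """Label genes UP / DOWN / SPECIAL / NS from their OVL/AUC statistics.

    Special genes are found in two steps: step 1 takes every gene inside the
    (OVL < ovl_max, auc_special_low < AUC < auc_special_high) band; step 2
    keeps only those whose kernel density is bimodal or multimodal in at
    least one group, recording which (``modality`` = C, E or B; step-1
    candidates resolved as unimodal carry U and are labelled NS).

    Returns a copy of ``stats`` with ``label`` and ``modality`` columns.
    """
    if thresholds is None:
        thresholds = SelectionThresholds()
    out = stats.copy()
    out["label"] = "NS"
    out["modality"] = ""
    undet = out["status"] != "ok"
    out.loc[undet, "label"] = "UNDETERMINED"
    low_ovl = out["ovl"] < thresholds.ovl_max
    up = ~undet & low_ovl & (out["auc"] >= thresholds.auc_up)
    down = ~undet & low_ovl & (out["auc"] <= thresholds.auc_down)
    cand = (
        ~undet
        & low_ovl
        & (out["auc"] > thresholds.auc_special_low)
        & (out["auc"] < thresholds.auc_special_high)
    )
    out.loc[up, "label"] = "UP"
    out.loc[down, "label"] = "DOWN"
    for gene_id in out.index[cand]:
        x, y = dataset.gene_pair(gene_id)
        dx = kde_grid(x, n_grid=n_grid, cut=cut, bandwidth_rule=bandwidth_rule)
        dy = kde_grid(y, n_grid=n_grid, cut=cut, bandwidth_rule=bandwidth_rule)
        label = label_from_flags(is_multimodal(dx), is_multimodal(dy))
        out.loc[gene_id, "modality"] = label
        if label != "U":
            out.loc[gene_id, "label"] = "SPECIAL"
    return out


def arrow_plot(
    stats: pd.DataFrame,
    output_path=None,
    thresholds: SelectionThresholds | None = None,
    ax=None,
):
    """Render the arrow plot: OVL on the x axis, AUC on the y axis.

    UP genes are red, DOWN blue; SPECIAL genes are orange (bimodal in the
    experimental group), cyan (control) or green (both); everything else
    gray.  Threshold guide lines are drawn when ``thresholds`` is given.
    Writes PNG/SVG when ``output_path`` is set; returns the axes.
    """
    import matplotlib

    if output_path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if thresholds is None:
        thresholds = SelectionThresholds()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    has_labels = "label" in stats.columns
    if len(stats):
        lab = stats["label"] if has_labels else pd.Series("NS", index=stats.index)
        mod = stats["modality"] if "modality" in stats.columns else pd.Series("", index=stats.index)
        key = lab.where(lab != "SPECIAL", "SPECIAL/" + mod)
        for name, color in _COLORS.items():
            sub = stats[key == name]
            if not len(sub):
                continue
            ax.scatter(
                sub["ovl"], sub["auc"], s=8, c=color, label=f"{name} ({len(sub)})",
                alpha=0.8, linewidths=0,
            )
        ax.legend(loc="center right", fontsize=8, frameon=False)
    for v in (thresholds.auc_up, thresholds.auc_down,
              thresholds.auc_special_low, thresholds.auc_special_high):
        ax.axhline(v, color="0.8", lw=0.7, zorder=0)
    ax.axvline(thresholds.ovl_max, color="0.8", lw=0.7, zorder=0)
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("OVL")
    ax.set_ylabel("AUC")
    ax.set_title("Arrow plot")
    if output_path is not None:
        ax.figure.savefig(output_path, dpi=150)
        plt.close(ax.figure)
    return ax


class ArrowPlot:
    """Arrow-plot model for a two-group expression dataset.

    Parameters
    ----------
    dataset : ExpressionDataset
        Log2 expression split into control and experimental groups.
    n_grid, cut, bandwidth_rule :
        Kernel-density settings shared by the OVL estimator and the
        bimodality detector (defaults: 512 grid points, 3 bandwidths of grid
        extension, adaptive bandwidth rule).
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        n_grid: int = 512,
        cut: float = 3.0,
        bandwidth_rule: str = "adaptive",
    ):
        self.dataset = dataset
        self.n_grid = int(n_grid)
        self.cut = float(cut)
        self.bandwidth_rule = bandwidth_rule

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, control_cols, experimental_cols, **kw):
        """Build the model from one matrix plus two column-name lists."""
        return cls(
            ExpressionDataset.from_dataframe(frame, control_cols, experimental_cols),
            **kw,
        )

    def fit(self) -> "ArrowPlotResults":
        """Compute per-gene OVL and AUC; returns the results object."""
        stats = compute_gene_stats(
            self.dataset, self.n_grid, self.cut, self.bandwidth_rule
        )
        return ArrowPlotResults(self, stats)


class ArrowPlotResults:
    """Fitted per-gene statistics plus selection, summary and plotting."""

    def __init__(self, model: ArrowPlot, gene_stats: pd.DataFrame):
        self.model = model
        self.gene_stats = gene_stats
        self.thresholds: SelectionThresholds | None = None
        self.selection: pd.DataFrame | None = None

    @property
    def n_undetermined(self) -> int:
        return int((self.gene_stats["status"] != "ok").sum())

    def select(self, thresholds: SelectionThresholds | None = None) -> pd.DataFrame:
        """Apply the selection rule; caches and returns the labelled table."""
        if thresholds is None:
            thresholds = SelectionThresholds()
        self.thresholds = thresholds
        self.selection = select_genes(
            self.gene_stats,
            self.model.dataset,
            thresholds,
            self.model.n_grid,
            self.model.cut,
            self.model.bandwidth_rule,
        )
        return self.selection

    def _labelled(self) -> pd.DataFrame:
        return self.selection if self.selection is not None else self.select()

    def label_counts(self) -> dict[str, int]:
        lab = self._labelled()["label"].value_counts()
        return {k: int(lab.get(k, 0)) for k in LABELS}

    def summary(self) -> str:
        """Text summary in the spirit of a fitted-model report."""
        sel = self._labelled()
        th = self.thresholds
        p, n, m = self.model.dataset.shape
        counts = self.label_counts()
        special = sel[sel["label"] == "SPECIAL"]
        lines = [
            "Arrow plot results",
            "=" * 50,
            f"Genes: {p}   arrays: {n} control / {m} experimental",
            f"KDE: {self.model.n_grid} grid points, cut={self.model.cut:g}, "
            f"bandwidth rule: {self.model.bandwidth_rule}",
            f"Thresholds: AUC>={th.auc_up:g} (up), AUC<={th.auc_down:g} (down), "
            f"{th.auc_special_low:g}<AUC<{th.auc_special_high:g} (special), "
            f"OVL<{th.ovl_max:g}",
            "-" * 50,
            f"UP: {counts['UP']}   DOWN: {counts['DOWN']}   "
            f"SPECIAL: {counts['SPECIAL']}   NS: {counts['NS']}   "
            f"undetermined: {counts['UNDETERMINED']}",
        ]
        if len(special):
            mc = special["modality"].value_counts()
            lines.append(
                "Special-gene bimodality: "
                f"control-only {int(mc.get('C', 0))}, "
                f"experimental-only {int(mc.get('E', 0))}, "
                f"both {int(mc.get('B', 0))}"
            )
            lines.append(
                f"Special OVL range: [{special['ovl'].min():.3f}, "
                f"{special['ovl'].max():.3f}], "
                f"AUC range: [{special['auc'].min():.3f}, "
                f"{special['auc'].max():.3f}]"
            )
        return "\n".join(lines)

    def to_table(self, path=None, sep: str = "\t") -> pd.DataFrame:
        """Result table (gene_id, OVL, AUC, modality_group, label).

        Rows are stable-sorted by label (UP, DOWN, SPECIAL, NS, UNDETERMINED)
        and ascending OVL within label; numbers carry 4 decimals on disk.
        """
        sel = self._labelled()
        table = pd.DataFrame(
            {
                "OVL": sel["ovl"],
                "AUC": sel["auc"],
                "modality_group": sel["modality"],
                "label": sel["label"],
            },
            index=sel.index,
        )
        order = {k: i for i, k in enumerate(LABELS)}
        table = table.sort_values(
            by=["label", "OVL"],
            key=lambda s: s.map(order) if s.name == "label" else s,
            kind="stable",
        )
        if path is not None:
            table.to_csv(path, sep=sep, float_format="%.4f", na_rep="NA")
        return table

    def plot(self, output_path=None, ax=None):
        """Render the arrow plot (see :func:`arrow_plot`)."""
        return arrow_plot(self._labelled(), output_path, self.thresholds, ax=ax)
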