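# arrowplot

Joint OVL/AUC selection of differentially expressed genes from two-group
expression data — including the "special" genes that mean-based statistics miss.

## The problem

In a two-group expression experiment (control vs experimental arrays, log2
scale), classical gene selection ranks genes by some distance between the
group means (fold change, t-statistics, ...). But biological samples are
heterogeneous: hidden subclasses — tumour subtypes, stimulation states,
genetic background — produce genes whose expression is **bimodal or
multimodal in one group while the group means barely differ**. Such genes
carry exactly the subgroup structure an experimenter wants to find, and every
mean-based statistic scores them as null.

`arrowplot` scores every gene with two nonparametric statistics:

* **OVL**, the overlapping coefficient of the two group densities,

  $$\mathrm{OVL} = \int \min\left[f_X(c),\, f_Y(c)\right]\,dc \in [0, 1],$$

  estimated from Gaussian-kernel densities with the adaptive bandwidth
  $h = (4/3)^{1/5}\,\min(s,\, R/1.34)\,n^{-1/5}$ (with $s$ the sample
  standard deviation and $R$ the interquartile range), via the pointwise
  minimum of the two grid densities plus their interpolated crossing points,
  integrated by a non-uniform trapezoidal rule;

* **AUC**, the area under the empirical ROC curve with the experimental group
  as the positive class, $\widehat{P}(Y > X)$, computed as the Mann-Whitney
  statistic (ties count 1/2).

Plotting OVL (x) against AUC (y) gives the *arrow plot*: up-regulated genes
cluster at (low OVL, AUC → 1), down-regulated at (low OVL, AUC → 0), and the
special genes at (low OVL, AUC ≈ 0.5). Selection is by rectangular
thresholds; the special band (default 0.4 < AUC < 0.6, OVL below the cutoff)
is then filtered by a kernel-density **bimodality test**: a density is called
multimodal when its grid ordinates rise in more than one contiguous run.
Genes surviving the filter are labelled by which group is bimodal (C/E/B).

Also included: the empirical-ROC comparison statistics **ABCR** (area between
the ROC curve and the rising diagonal, summed over equal-width slices as
$\sum_k |AUC_k - A_k|$ with $A_k = (2k-1)/(2m_0^2)$) and **TNRC**
(ABCR $- |AUC - \tfrac12|$, large for "not proper", diagonal-crossing ROC
curves); a lognormal **simulator** with ground-truth labels for the four gene
classes; and a **benchmark** module that scores any gene-ranking statistic by
how well it separates true DE genes from nulls.

## Worked example

```python
from arrowplot import ArrowPlot, SelectionThresholds, SimConfig, simulate_dataset

config = SimConfig(seed=1).scaled(2000)   # 1900 null / 45 up / 45 down / 10 special
dataset, truth = simulate_dataset(config)

results = ArrowPlot(dataset).fit()        # per-gene OVL and AUC
results.select(SelectionThresholds.simulated())   # OVL < 0.3 preset
print(results.summary())
```

```
Arrow plot results
==================================================
Genes: 2000   arrays: 30 control / 30 experimental
KDE: 512 grid points, cut=3, bandwidth rule: adaptive
Thresholds: AUC>=0.9 (up), AUC<=0.1 (down), 0.4<AUC<0.6 (special), OVL<0.3
--------------------------------------------------
UP: 45   DOWN: 44   SPECIAL: 5   NS: 1906   undetermined: 0
Special-gene bimodality: control-only 0, experimental-only 3, both 2
Special OVL range: [0.209, 0.289], AUC range: [0.433, 0.564]
```

All 45 true up-regulated genes and 44/45 down-regulated genes are recovered;
4 of the 10 mixture-distributed special genes pass both steps (the others
have mixture components too close together to clear the OVL cutoff — the
known cost of the double-filter design), and one unequal-variance null gene
slips past the bimodality filter into the SPECIAL list. `results.to_table("selection.tsv")`
writes the per-gene table (OVL, AUC, modality group, label; sorted by
ascending OVL within label) and `results.plot("arrow.png")` draws the arrow
plot with the selected genes coloured (UP red, DOWN blue, SPECIAL
orange/cyan/green by bimodal group).

The same pipeline runs from the shell:

```bash
arrowplot simulate --seed 1 --p-total 2000 --n-up 45 --n-down 45 --n-special 10 --out-dir sim
arrowplot select sim/expression.tsv --groups sim/groups.tsv --preset simulated \
    --out selection.tsv --plot-file arrow.png
arrowplot compare sim/expression.tsv --groups sim/groups.tsv   # per-gene AUC/ABCR/TNRC
```

For real data, `arrowplot select matrix.tsv --groups groups.tsv --impute-k 10`
reads a genes × arrays TSV/CSV (gene IDs in column 1, missing entries empty
or `NA`) with a two-column sample/group assignment file, optionally imputing
missing values gene-wise by k-nearest neighbours.

## Layout

| module | contents |
| --- | --- |
| `arrowplot.model` | `ArrowPlot` / `ArrowPlotResults`, thresholds, selection, arrow plot |
| `arrowplot.kde` | Gaussian KDE, adaptive + normal-reference bandwidths |
| `arrowplot.ovl` | overlapping-coefficient estimator (min envelope, crossings, trapezoid) |
| `arrowplot.roc` | Mann-Whitney AUC, empirical ROC, ABCR, TNRC |
| `arrowplot.modality` | grid-ordinate bimodality detector |
| `arrowplot.simulate` | lognormal simulation design with ground truth |
| `arrowplot.benchmark` | method-performance ROC evaluation, baseline scores |
| `arrowplot.datasets` | expression-matrix I/O, group files, KNN imputation |
| `arrowplot.cli` | `arrowplot` command-line interface |

See `docs/methods.md` for the statistical details, parameter defaults and
known limitations.
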