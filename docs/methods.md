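# Methods

This note documents the statistical machinery behind `arrowplot`: the
estimators, their numerical conventions, the synthetic-data design, and the
places where the design was genuinely open and a choice had to be made.

## Per-gene statistics

### Kernel density estimation (`arrowplot.kde`)

Each group's expression vector (log2 scale, missing values dropped, at least
two finite values required) is smoothed with the fixed-bandwidth Gaussian
kernel estimator

    f_hat(x) = (1 / (n h)) Σ_i φ((x − x_i) / h),

evaluated on 512 equally spaced points spanning `[min − 3h, max + 3h]`.
Both the grid size and the 3-bandwidth extension (`n_grid`, `cut`) are
configurable; the defaults mirror the long-standing defaults of R's
`density()`, and a direct test pins our ordinates to R's within 2e-3 (R
approximates the kernel sum by FFT binning, we evaluate it exactly).

The default bandwidth is the adaptive-spread rule

    h = (4/3)^(1/5) · min(s, R/1.34) · n^(−1/5),

with `s` the sample standard deviation (ddof = 1) and `R` the interquartile
range from linear-interpolation quantiles (the common statistical default;
configurable, with only mild effect on `h`). Taking the minimum of the two
spread measures matters here: the plain normal-reference rule
`h = (4/3)^(1/5) s n^(−1/5)` (available as `bandwidth_rule=
"normal_reference"`) over-smooths multimodal samples, and downstream
modality detection reads peaks straight off the ordinates. If the IQR is
zero but `s > 0` (heavy central ties) the rule falls back to `s`; a sample
with zero spread raises a degenerate-sample error, which the pipeline
converts into an `undetermined` gene rather than aborting the run.

### Overlapping coefficient (`arrowplot.ovl`)

OVL = ∫ min(f_X, f_Y) is estimated from the two grid densities by

1. evaluating both densities on the union of their grids (linear
   interpolation off-grid, zero outside a density's own grid — the grids
   already extend three bandwidths past the data, where a Gaussian kernel is
   negligible, so zero-extension is the consistent completion);
2. taking the pointwise minimum;
3. adding the interpolated crossing points of the two piecewise-linear
   densities wherever `sign(f_A − f_B)` changes strictly between adjacent
   union-grid abscissas (tangential contact without a sign change is not a
   crossing, which avoids duplicated points);
4. sorting by abscissa, resolving duplicate abscissas to the minimum
   ordinate, and integrating with the trapezoidal rule on the resulting
   non-uniform grid.

The result is clipped to [0, 1] to guard against interpolation overshoot.
The estimator is symmetric by construction and agrees with a brute-force
oracle (both KDEs on one shared 10001-point grid, pointwise minimum,
trapezoid) to 1e-3 on random sample pairs; boundary artifacts of the
zero-extension are negligible for kernel densities but make the routine
unsuitable for densities with abrupt support edges.

### ROC statistics (`arrowplot.roc`)

AUC is the Mann-Whitney estimator of P(Y > X) with ties counted 1/2,
computed from pooled midranks. The orientation is fixed package-wide:
experimental = positive class, values above the threshold = positive call,
so AUC → 1 means up-regulation. It is never auto-flipped, because curves
below or crossing the diagonal are informative (equal-mean genes with
bimodal or unequal-variance distributions produce them).

The empirical ROC curve takes every distinct pooled value as a threshold;
its trapezoidal area equals the Mann-Whitney statistic exactly (Bamber's
identity, asserted to 1e-12 in the tests, ties included).

ABCR sums |partial ROC area − partial chance area| over m₀ equal-width
slices of the FPR axis, where m₀ is the number of distinct pooled values and
the chance partial areas are (2k−1)/(2m₀²). The equal-width-slice reading is
the one under which the chance terms are exactly the diagonal's slice areas
and the sum telescopes to |AUC − 1/2| for curves that never cross the
diagonal; with ties, distinct pooled values define the slices. TNRC =
ABCR − |AUC − 1/2| is then ~0 for any one-sided curve and grows with
diagonal crossings (sigmoidal shape). Both require at least two distinct
pooled values.

### Bimodality detection (`arrowplot.modality`)

Grid ordinates are scanned once: position i is "rising" when
`y[i] <= y[i+1]` (plateaus count as rising and never split a run). The
density is multimodal iff the rising positions form more than one contiguous
run. There is no prominence threshold and no extra smoothing — the adaptive
bandwidth is the only noise control. Consequences worth knowing:

* a mode at the extreme left grid edge is invisible to the forward scan;
  irrelevant for KDE grids, which rise from ~0 at both ends;
* the verdict is reflection-invariant for tie-free interior-peaked
  ordinates (property-tested), but exact ordinate ties at a run boundary
  resolve in scan direction;
* at n = 30 the rule is deliberately trigger-happy: ~24% of unimodal normal
  samples show a genuine secondary bump in their kernel density and are
  flagged (the narrower normal-reference-bandwidth variant used by R's
  defaults flags ~49%). Separated mixtures (≥ 5 sd between components) are
  detected essentially always. The selection pipeline only ever applies the
  detector to step-1 candidates, so this false-positive rate touches only
  genes already inside the (low OVL, AUC ≈ 0.5) band.

## Selection (`arrowplot.model`)

Boundary conventions: UP requires `AUC >= auc_up` and `OVL < ovl_max`; DOWN
`AUC <= auc_down` and `OVL < ovl_max`; the special band is open
(`auc_special_low < AUC < auc_special_high`) with the same strict OVL cut.
Step 2 keeps a special candidate only if at least one group's density is
multimodal, recording which (C/E/B); candidates resolved unimodal fall back
to NS. Defaults are `0.9 / 0.1 / 0.4 / 0.6` with `ovl_max = 0.5`
(`SelectionThresholds.lymphoma()`); the synthetic-data analyses use the
stricter `ovl_max = 0.3` (`SelectionThresholds.simulated()`). Both are
presets because the appropriate OVL cut is data-dependent — this is an
exploratory tool, and no FDR calibration is attached to the thresholds by
design. Genes whose statistics cannot be computed (a constant group) are
labelled UNDETERMINED and reported, never dropped; labels partition the gene
set, relaxing `ovl_max` upward can only grow the UP/DOWN/candidate sets, and
step 2 can only shrink the special set (all property-tested).

## Synthetic data (`arrowplot.simulate`)

The generator emulates a two-group spotted-microarray study: per gene and
group, values are drawn lognormal and then log-transformed, so on the
analysis scale each group is Gaussian with location μ and scale σ. Defaults
(10000 genes, 30 arrays per group; 9500 null / 225 up / 225 down / 50
special) are the study conditions of the simulation design the package
reproduces; `SimConfig.scaled(p)` shrinks the gene count with proportions
preserved.

* Baseline: every unimodal group sits at location 3.5 with log-scale
  variance 1.
* NULL genes: the experimental location differs by U(−0.9, 0.9).
* UP / DOWN genes: the higher group's location differs by U(3.5, 13.5)
  (experimental higher for UP, control for DOWN), so case locations span
  [7, 17] — deliberately the same range as the special genes' upper mixture
  component.
* Variance heterogeneity: a minority of genes (`heteroscedastic_fraction`,
  default 0.1) draw a variance difference U(0, 12.25) added to the base
  variance on a randomly chosen side; the rest are homoscedastic. The stated
  range describes how far variances can differ, not how often: making every
  gene heteroscedastic floods the low-OVL region with null genes and is
  irreconcilable with the selection behaviour this design is meant to
  exhibit (nearly clean separation of DE genes by OVL alone). The 0.1 share
  makes variance-driven confounders present but minority, which is also the
  realistic reading for arrays of a homogeneous tissue contrast.
* SPECIAL genes: one group (chosen at random, recorded) is the mixture
  0.5·logN(3.5, 1.2) + 0.5·logN(μ₁, 1.2) with μ₁ ~ U(7, 17) and a binomial
  component split; the other group is unimodal logN at the mixture's mean
  location 0.5·3.5 + 0.5·μ₁ with the same σ = 1.2. The two groups therefore
  share their log-scale mean (AUC ≈ 0.5) but differ in shape. Genes with μ₁
  near 7 have weakly separated components and substantial OVL — they are the
  special genes the pipeline legitimately misses, and the reason recovery
  sits near 95% rather than 100%.

Reproducibility: each gene draws from a counter-based substream spawned from
`(seed, gene index)`, so a given seed is bit-reproducible and extending
`p_total` (at fixed class counts) appends genes without reshuffling earlier
ones.

What the generator does **not** emulate: gene–gene correlation (sampling is
independent by design), array-level normalisation artifacts, missing values,
and intensity-dependent variance. Passing tests on this design therefore
demonstrate the estimators and the selection logic, not robustness to those
real-data complications; the KNN-imputation hook and the threshold presets
exist precisely because real two-channel data needs both.

## Benchmarking (`arrowplot.benchmark`)

`performance_auc` scores a per-gene statistic by the empirical AUC with
which it separates truly DE genes (positives) from truly null genes
(negatives). Scores are first oriented: OVL is negated (low = DE), signed
mean-difference statistics are folded by absolute value, AUC-statistic
scores by max(a, 1−a). In the special-genes-only scenario the up/down genes
are excluded from the evaluation set entirely (they are neither positives
nor negatives); this exclusion is a documented reading, recorded in the
report metadata, since pooling them with the negatives would penalise
methods for detecting genuine differential expression. Built-in baselines:
FC (log2 ratio of raw-scale group means), AD (mean difference of the log
values), Welch t, OVL and the folded AUC statistic; published moderated-t
variants and similar are accepted as external score files rather than
re-implemented.

`simulation_study()` packages the whole evaluation (generate, fit, select,
score) and is what `scripts/acceptance.py` averages over three seeds. At the
default design size a single study takes ~10 s on one CPU; the reduced
2000-gene variant used in the fast tests keeps the class proportions.

## Known limitations

* OVL inherits KDE bias: at n = 30 the estimate of identical groups
  undershoots 1 slightly, and heavily smoothed mixtures (large IQR inflating
  the bandwidth) blur into their unimodal counterparts.
* The bimodality rule is threshold-free; sub-grid or near-machine-precision
  wiggles are taken at face value. No tolerance is added, deliberately.
* ABCR/TNRC with ties follows the distinct-pooled-values reading; other
  readings of the tie handling exist and differ in the third decimal on
  small samples.
* Thresholds are exploratory, not inferential: no error-rate control is
  claimed for the selected lists.
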