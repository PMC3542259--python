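"""Synthetic two-group microarray data with known differential-expression truth.

The generator emulates a classical spotted-microarray simulation design:
expression values are drawn from lognormal distributions per gene and group
and then log-transformed, so on the analysis (log) scale each group is normal
with location mu and scale sigma.  A dataset of ``p_total`` genes contains
four classes in exact counts:

* NULL — no differential expression: the group locations differ by a uniform
  draw in ``null_mean_diff_range`` (default [-0.9, 0.9]).  A minority of
  genes (``heteroscedastic_fraction``) additionally differ in spread: their
  log-scale variances differ by a uniform draw in ``null_var_diff_range``
  (default [0, 12.25], added to a base variance of 1 on a randomly chosen
  side); the remaining genes are homoscedastic.  Genes with significantly
  different group variances superficially resemble special genes, which is
  exactly the confound the bimodality step removes.
* UP / DOWN — the experimental (resp. control) location exceeds the other
  group's by a uniform draw in ``de_mean_diff_range`` (default [3.5, 13.5]);
  variances as for NULL.
* SPECIAL — one group (chosen at random and recorded) is a two-component
  lognormal mixture alpha*logN(mu0, sigma) + (1-alpha)*logN(mu1, sigma) with
  mu0 = 3.5, mu1 uniform in [7, 17], sigma = 1.2, alpha = 0.5; the other
  group is unimodal lognormal with location alpha*mu0 + (1-alpha)*mu1 and the
  same sigma, so the two groups share their (log-scale) mean but differ in
  shape — the "hidden subclasses" scenario that mean-based tests miss.

Reproducibility: each gene draws from its own counter-based substream spawned
from the root seed and the gene index, so the values of gene ``i`` do not
depend on ``p_total`` and identical seeds give bit-identical matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, write_group_file

__all__ = ["SimConfig", "SimTruth", "simulate_dataset", "write_fixture", "read_truth"]

NULL, UP, DOWN, SPECIAL = "NULL", "UP", "DOWN", "SPECIAL"
CLASSES = (NULL, UP, DOWN, SPECIAL)

#: base log-scale location shared by all unimodal baselines
_BASE_MU = 3.5
#: base log-scale variance of the smaller-variance group
_BASE_VAR = 1.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic dataset generator (log-scale units)."""

    p_total: int = 10000
    n_per_group: int = 30
    n_up: int = 225
    n_down: int = 225
    n_special: int = 50
    null_mean_diff_range: tuple[float, float] = (-0.9, 0.9)
    null_var_diff_range: tuple[float, float] = (0.0, 12.25)
    de_mean_diff_range: tuple[float, float] = (3.5, 13.5)
    de_var_diff_range: tuple[float, float] = (0.0, 12.25)
    special_mu0: float = 3.5
    special_mu1_range: tuple[float, float] = (7.0, 17.0)
    special_sigma: float = 1.2
    special_alpha: float = 0.5
    heteroscedastic_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_up, self.n_down, self.n_special)
        if any(c < 0 for c in counts) or sum(counts) > self.p_total:
            raise ValueError("class counts must be >= 0 and sum to <= p_total")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 arrays per group")
        for name in (
            "null_mean_diff_range",
            "null_var_diff_range",
            "de_mean_diff_range",
            "de_var_diff_range",
            "special_mu1_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lower bound exceeds upper bound")
        if not 0.0 < self.special_alpha < 1.0:
            raise ValueError("special_alpha must be in (0, 1)")
        if not 0.0 <= self.heteroscedastic_fraction <= 1.0:
            raise ValueError("heteroscedastic_fraction must be in [0, 1]")
        if self.special_sigma <= 0:
            raise ValueError("special_sigma must be positive")

    @property
    def n_null(self) -> int:
        return self.p_total - self.n_up - self.n_down - self.n_special

    def scaled(self, p_total: int) -> "SimConfig":
        """Same design at a different size, class proportions preserved."""
        f = p_total / self.p_total
        return SimConfig(
            **{
                **asdict(self),
                "p_total": p_total,
                "n_up": round(self.n_up * f),
                "n_down": round(self.n_down * f),
                "n_special": round(self.n_special * f),
            }
        )


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset.

    ``frame`` is indexed by gene_id with columns: ``class`` (NULL/UP/DOWN/
    SPECIAL), per-group log-scale locations and scales (``mu_control``,
    ``mu_experimental``, ``sigma_control``, ``sigma_experimental``) and, for
    SPECIAL genes, ``mixture_group`` ('control'/'experimental'), ``mu0``,
    ``mu1``, ``alpha``.
    """

    frame: pd.DataFrame
    seed: int
    config: SimConfig

    def classes(self) -> pd.Series:
        return self.frame["class"]

    def counts(self) -> dict[str, int]:
        c = self.classes().value_counts()
        return {k: int(c.get(k, 0)) for k in CLASSES}

    def de_gene_ids(self) -> pd.Index:
        return self.frame.index[self.frame["class"] != NULL]


def _gene_classes(config: SimConfig) -> list[str]:
    return (
        [UP] * config.n_up
        + [DOWN] * config.n_down
        + [SPECIAL] * config.n_special
        + [NULL] * config.n_null
    )


def _draw_variances(rng, var_diff_range, hetero_fraction) -> tuple[float, float]:
    """Log-scale sigmas for (control, experimental); larger side random.

    With probability ``hetero_fraction`` the gene is heteroscedastic and the
    variance difference is drawn uniformly from ``var_diff_range``; otherwise
    both groups share the base variance.
    """
    hetero = rng.random() < hetero_fraction
    dv = rng.uniform(*var_diff_range)
    if not hetero:
        dv = 0.0
    big_is_control = rng.random() < 0.5
    s_small = np.sqrt(_BASE_VAR)
    s_big = np.sqrt(_BASE_VAR + dv)
    return (s_big, s_small) if big_is_control else (s_small, s_big)


def _simulate_gene(rng, klass: str, config: SimConfig):
    """Raw-scale (lognormal) value vectors plus the generating parameters."""
    n = config.n_per_group
    rec = {
        "class": klass,
        "mixture_group": "",
        "mu0": np.nan,
        "mu1": np.nan,
        "alpha": np.nan,
    }
    if klass == SPECIAL:
        sig = config.special_sigma
        mu1 = rng.uniform(*config.special_mu1_range)
        alpha = config.special_alpha
        mix_in_control = rng.random() < 0.5
        n_comp0 = rng.binomial(n, alpha)
        mix = np.concatenate(
            [
                rng.lognormal(config.special_mu0, sig, size=n_comp0),
                rng.lognormal(mu1, sig, size=n - n_comp0),
            ]
        )
        rng.shuffle(mix)
        mu_uni = alpha * config.special_mu0 + (1.0 - alpha) * mu1
        uni = rng.lognormal(mu_uni, sig, size=n)
        control, experimental = (mix, uni) if mix_in_control else (uni, mix)
        rec.update(
            mixture_group="control" if mix_in_control else "experimental",
            mu0=config.special_mu0,
            mu1=mu1,
            alpha=alpha,
            mu_control=mu_uni if not mix_in_control else np.nan,
            mu_experimental=mu_uni if mix_in_control else np.nan,
            sigma_control=sig,
            sigma_experimental=sig,
        )
        return control, experimental, rec

    if klass == NULL:
        dmu = rng.uniform(*config.null_mean_diff_range)
        mu_c, mu_e = _BASE_MU, _BASE_MU + dmu
        var_range = config.null_var_diff_range
    elif klass == UP:
        dmu = rng.uniform(*config.de_mean_diff_range)
        mu_c, mu_e = _BASE_MU, _BASE_MU + dmu
        var_range = config.de_var_diff_range
    elif klass == DOWN:
        dmu = rng.uniform(*config.de_mean_diff_range)
        mu_c, mu_e = _BASE_MU + dmu, _BASE_MU
        var_range = config.de_var_diff_range
    else:  # pragma: no cover
        raise ValueError(f"unknown gene class {klass!r}")
    sig_c, sig_e = _draw_variances(rng, var_range, config.heteroscedastic_fraction)
    control = rng.lognormal(mu_c, sig_c, size=n)
    experimental = rng.lognormal(mu_e, sig_e, size=n)
    rec.update(
        mu_control=mu_c,
        mu_experimental=mu_e,
        sigma_control=sig_c,
        sigma_experimental=sig_e,
    )
    return control, experimental, rec


def simulate_dataset(config: SimConfig | None = None, **overrides):
    """Generate one synthetic dataset plus its ground truth.

    Values are drawn on the raw (lognormal) scale and then log-transformed,
    so the returned :class:`~arrowplot.datasets.ExpressionDataset` holds
    normally distributed log expression per gene and group.

    Returns
    -------
    (ExpressionDataset, SimTruth)
    """
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        config = SimConfig(**{**asdict(config), **overrides})
    classes = _gene_classes(config)
    width = max(5, len(str(config.p_total)))
    gene_ids = [f"G{i:0{width}d}" for i in range(1, config.p_total + 1)]
    control = np.empty((config.p_total, config.n_per_group))
    experimental = np.empty((config.p_total, config.n_per_group))
    records = []
    for i, klass in enumerate(classes):
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(config.seed, spawn_key=(i,)))
        )
        c_raw, e_raw, rec = _simulate_gene(rng, klass, config)
        control[i] = np.log(c_raw)
        experimental[i] = np.log(e_raw)
        records.append(rec)
    idx = pd.Index(gene_ids, name="gene_id")
    cols_c = [f"C{j:02d}" for j in range(1, config.n_per_group + 1)]
    cols_e = [f"E{j:02d}" for j in range(1, config.n_per_group + 1)]
    dataset = ExpressionDataset(
        control=pd.DataFrame(control, index=idx, columns=cols_c),
        experimental=pd.DataFrame(experimental, index=idx, columns=cols_e),
    )
    truth = SimTruth(
        frame=pd.DataFrame(records, index=idx), seed=config.seed, config=config
    )
    return dataset, truth


def write_fixture(dataset: ExpressionDataset, truth: SimTruth, directory) -> dict:
    """Write expression matrix, group assignment and truth table as TSV.

    Returns the mapping of logical names to file paths; the files round-trip
    losslessly through :func:`arrowplot.datasets.read_expression_matrix` /
    :func:`read_truth`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "groups": directory / "groups.tsv",
        "truth": directory / "truth.tsv",
    }
    dataset.write(paths["expression"], float_format="%.10g")
    write_group_file(dataset.groups(), paths["groups"])
    truth.frame.to_csv(paths["truth"], sep="\t", na_rep="NA")
    return paths


def read_truth(path) -> pd.DataFrame:
    """Read back a truth table written by :func:`write_fixture`."""
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
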