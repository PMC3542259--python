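"""Two-group expression datasets and their on-disk TSV/CSV representation.

The on-disk layout mirrors the common two-channel microarray export: genes as
rows with the identifier in the first column, arrays as columns, values on a
log2 scale, missing entries empty or ``NA``.  Group membership (control vs
experimental) is given either programmatically or as a two-column assignment
file ``sample<TAB>group``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "read_expression_matrix",
    "read_group_file",
    "write_group_file",
    "knn_impute",
]

CONTROL = "control"
EXPERIMENTAL = "experimental"
_NA_VALUES = ["", "NA", "NaN", "nan", "null"]


@dataclass
class ExpressionDataset:
    """A genes x arrays expression matrix split into two groups.

    Attributes
    ----------
    control, experimental : pandas.DataFrame
        Log2 expression values, genes as the (shared, unique) row index and
        arrays as columns; missing values as NaN.
    """

    control: pd.DataFrame
    experimental: pd.DataFrame

    def __post_init__(self) -> None:
        c, e = self.control, self.experimental
        if not c.index.equals(e.index):
            raise ValueError("control and experimental gene indexes differ")
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dup[:5]}")
        if c.shape[1] < 2 or e.shape[1] < 2:
            raise ValueError("each group needs at least 2 arrays")
        self.control = c.astype(float)
        self.experimental = e.astype(float)

    @property
    def gene_ids(self) -> pd.Index:
        return self.control.index

    @property
    def n_genes(self) -> int:
        return self.control.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        """(genes, control arrays, experimental arrays)."""
        return (self.n_genes, self.control.shape[1], self.experimental.shape[1])

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, control_cols, experimental_cols
    ) -> "ExpressionDataset":
        """Split a genes x arrays frame by explicit column-name lists."""
        missing = [c for c in [*control_cols, *experimental_cols] if c not in frame.columns]
        if missing:
            raise KeyError(f"columns not in matrix: {missing[:5]}")
        return cls(
            control=frame[list(control_cols)].copy(),
            experimental=frame[list(experimental_cols)].copy(),
        )

    def gene_pair(self, gene_id) -> tuple[np.ndarray, np.ndarray]:
        """Finite control/experimental value vectors for one gene."""
        x = self.control.loc[gene_id].to_numpy(dtype=float)
        y = self.experimental.loc[gene_id].to_numpy(dtype=float)
        return x[np.isfinite(x)], y[np.isfinite(y)]

    def to_frame(self) -> pd.DataFrame:
        """Recombine the two groups into one matrix (control columns first)."""
        return pd.concat([self.control, self.experimental], axis=1)

    def write(self, path, sep: str = "\t", float_format: str = "%.6g") -> None:
        """Write the combined matrix as TSV/CSV with gene IDs in column 1."""
        frame = self.to_frame()
        frame.index.name = frame.index.name or "gene_id"
        frame.to_csv(path, sep=sep, float_format=float_format, na_rep="NA")

    def groups(self) -> pd.Series:
        """Sample -> group assignment series covering all columns."""
        return pd.Series(
            {**{c: CONTROL for c in self.control.columns},
             **{c: EXPERIMENTAL for c in self.experimental.columns}},
            name="group",
        )


def _detect_sep(path: Path) -> str:
    head = path.open("r", encoding="utf-8", errors="replace").readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_expression_matrix(path, groups, sep: str | None = None) -> ExpressionDataset:
    """Read a genes x arrays matrix and split its columns into two groups.

    Parameters
    ----------
    path : str or Path
        TSV or CSV file, gene IDs in the first column, one header row.
    groups : mapping/Series sample->group, or (control_cols, experimental_cols)
        Group specification; group names must be ``control`` and
        ``experimental`` (case-insensitive) when given as a mapping.
    sep : str, optional
        Field delimiter; auto-detected from the header when omitted.

    Raises
    ------
    ValueError
        On duplicate gene IDs or unparseable content.
    KeyError
        If the group spec names columns absent from the matrix.
    """
    path = Path(path)
    if sep is None:
        sep = _detect_sep(path)
    try:
        frame = pd.read_csv(
            path, sep=sep, index_col=0, na_values=_NA_VALUES, keep_default_na=False
        )
    except Exception as exc:  # surface the pandas line context
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs in {path}: {dup[:5]}")
    if isinstance(groups, tuple) and len(groups) == 2:
        control_cols, experimental_cols = groups
    else:
        assign = pd.Series(groups).astype(str).str.lower().str.strip()
        control_cols = assign.index[assign == CONTROL].tolist()
        experimental_cols = assign.index[assign == EXPERIMENTAL].tolist()
        bad = assign[~assign.isin([CONTROL, EXPERIMENTAL])]
        if len(bad):
            raise ValueError(
                f"unknown group labels {sorted(bad.unique())}; "
                f"expected '{CONTROL}' or '{EXPERIMENTAL}'"
            )
    return ExpressionDataset.from_dataframe(frame, control_cols, experimental_cols)


def read_group_file(path, sep: str | None = None) -> pd.Series:
    """Read a two-column ``sample<TAB>group`` assignment file."""
    path = Path(path)
    if sep is None:
        sep = _detect_sep(path)
    frame = pd.read_csv(path, sep=sep, header=0)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample, group)")
    return pd.Series(frame.iloc[:, 1].values, index=frame.iloc[:, 0].astype(str), name="group")


def write_group_file(groups: pd.Series, path, sep: str = "\t") -> None:
    frame = pd.DataFrame({"sample": groups.index, "group": groups.values})
    frame.to_csv(path, sep=sep, index=False)


def knn_impute(frame: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Gene-wise k-nearest-neighbour imputation of missing expression values.

    A gene's missing entry is filled from the ``k`` genes closest to it in
    Euclidean distance over the arrays both genes observe (the standard
    microarray imputation preprocessing).  Rows with no missing values are
    untouched.  This is a preprocessing hook for externally distributed
    datasets; the simulator never produces missing values.
    """
    from sklearn.impute import KNNImputer

    if not frame.isna().to_numpy().any():
        return frame.copy()
    # orient genes as "samples" so neighbours are other genes
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    values = imputer.fit_transform(frame.to_numpy(dtype=float))
    return pd.DataFrame(values, index=frame.index, columns=frame.columns)
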