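import numpy as np
import pandas as pd
import pytest

from arrowplot import ArrowPlot, SimConfig, simulate_dataset
from arrowplot.datasets import ExpressionDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20201)


@pytest.fixture(scope="session")
def small_sim():
    """A 600-gene dataset with the default class proportions (seed 7)."""
    return simulate_dataset(SimConfig(seed=7).scaled(600))


@pytest.fixture(scope="session")
def small_sim_results(small_sim):
    dataset, _ = small_sim
    return ArrowPlot(dataset).fit()


def toy_dataset(control_rows, experimental_rows, gene_ids=None):
    """Build a small ExpressionDataset from per-gene value lists."""
    control_rows = [np.asarray(r, dtype=float) for r in control_rows]
    experimental_rows = [np.asarray(r, dtype=float) for r in experimental_rows]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(len(control_rows))]
    idx = pd.Index(gene_ids, name="gene_id")
    return ExpressionDataset(
        control=pd.DataFrame(control_rows, index=idx),
        experimental=pd.DataFrame(experimental_rows, index=idx),
    )
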