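import numpy as np
import pytest

from arrowplot import ArrowPlot, SelectionThresholds
from arrowplot.model import arrow_plot, select_genes

from conftest import toy_dataset


class TestSelectionThresholds:
    def test_defaults_and_presets(self):
        assert SelectionThresholds().ovl_max == 0.5
        assert SelectionThresholds.lymphoma().ovl_max == 0.5
        assert SelectionThresholds.simulated().ovl_max == 0.3

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"auc_up": 0.3},  # ordering violated
            {"auc_down": 0.5},
            {"ovl_max": 0.0},
            {"ovl_max": 1.5},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            SelectionThresholds(**kwargs)


class TestComputeGeneStats:
    def test_toy_dataset(self, rng):
        base = rng.normal(0, 1, 10)
        ds = toy_dataset(
            control_rows=[base, base],
            experimental_rows=[base + 50.0, base],
        )
        stats = ArrowPlot(ds).fit().gene_stats
        assert stats.loc["g0", "auc"] == 1.0
        assert stats.loc["g0", "ovl"] < 0.01
        assert stats.loc["g1", "auc"] == 0.5
        assert stats.loc["g1", "ovl"] == pytest.approx(1.0, abs=0.01)

    def test_constant_group_marked_undetermined(self, rng):
        ds = toy_dataset(
            control_rows=[np.full(6, 2.0), rng.normal(0, 1, 6)],
            experimental_rows=[rng.normal(0, 1, 6), rng.normal(0, 1, 6)],
        )
        stats = ArrowPlot(ds).fit().gene_stats
        assert stats.loc["g0", "status"] == "undetermined"
        assert np.isnan(stats.loc["g0", "ovl"])
        assert stats.loc["g1", "status"] == "ok"

    def test_missing_values_dropped_per_gene(self, rng):
        row = rng.normal(0, 1, 8)
        row_missing = row.copy()
        row_missing[:2] = np.nan
        ds = toy_dataset([row_missing], [row + 3.0])
        stats = ArrowPlot(ds).fit().gene_stats
        assert stats.loc["g0", "n_control"] == 6
        assert stats.loc["g0", "status"] == "ok"


class TestSelectGenes:
    def test_threshold_regions(self, rng):
        base = rng.normal(0, 0.5, 30)
        ds = toy_dataset(
            control_rows=[base, base, base],
            experimental_rows=[base + 5.0, base - 5.0, base + 0.01],
            gene_ids=["up", "down", "flat"],
        )
        res = ArrowPlot(ds).fit()
        sel = res.select(SelectionThresholds())
        assert sel.loc["up", "label"] == "UP"
        assert sel.loc["down", "label"] == "DOWN"
        assert sel.loc["flat", "label"] == "NS"  # high overlap

    def test_special_two_step(self):
        rng = np.random.default_rng(1)  # draw where both verdicts are clean
        mix = np.concatenate([rng.normal(-10, 1, 15), rng.normal(10, 1, 15)])
        uni_wide = rng.normal(0, 7, 30)  # unequal variance, unimodal
        uni_narrow = rng.normal(0, 1, 30)
        ds = toy_dataset(
            control_rows=[uni_narrow, uni_narrow],
            experimental_rows=[mix, uni_wide],
            gene_ids=["special", "hetero_null"],
        )
        res = ArrowPlot(ds).fit()
        sel = res.select(SelectionThresholds())
        # both genes sit in the step-1 band (AUC ~ 0.5, OVL < 0.5) ...
        assert (sel["modality"] != "").all()
        # ... but only the mixture gene survives the bimodality step
        assert sel.loc["special", "label"] == "SPECIAL"
        assert sel.loc["special", "modality"] == "E"
        assert sel.loc["hetero_null", "label"] == "NS"
        assert sel.loc["hetero_null", "modality"] == "U"

    def test_labels_partition_genes(self, small_sim_results):
        sel = small_sim_results.select(SelectionThresholds.simulated())
        counts = sel["label"].value_counts()
        assert counts.sum() == len(sel)
        assert set(counts.index) <= {"UP", "DOWN", "SPECIAL", "NS", "UNDETERMINED"}

    def test_relaxing_ovl_only_adds_genes(self, small_sim_results):
        res = small_sim_results
        tight = res.select(SelectionThresholds(ovl_max=0.3))
        loose = res.select(SelectionThresholds(ovl_max=0.5))
        for label in ("UP", "DOWN"):
            assert set(tight.index[tight["label"] == label]) <= set(
                loose.index[loose["label"] == label]
            )
        # step-1 candidates (any gene with a modality verdict) also only grow
        assert set(tight.index[tight["modality"] != ""]) <= set(
            loose.index[loose["modality"] != ""]
        )

    def test_step2_only_shrinks_candidates(self, small_sim_results):
        sel = small_sim_results.select(SelectionThresholds.simulated())
        special = set(sel.index[sel["label"] == "SPECIAL"])
        candidates = set(sel.index[sel["modality"] != ""])
        assert special <= candidates


class TestResultsSurface:
    def test_summary_reports_counts(self, small_sim_results):
        res = small_sim_results
        res.select(SelectionThresholds.simulated())
        text = res.summary()
        counts = res.label_counts()
        assert f"UP: {counts['UP']}" in text
        assert f"SPECIAL: {counts['SPECIAL']}" in text
        assert "OVL<0.3" in text

    def test_table_sorted_by_ovl_within_label(self, small_sim_results, tmp_path):
        res = small_sim_results
        res.select(SelectionThresholds.simulated())
        path = tmp_path / "table.tsv"
        table = res.to_table(path)
        assert path.exists()
        for _, block in table.groupby("label", sort=False):
            ovl_vals = block["OVL"].dropna().to_numpy()
            assert np.all(np.diff(ovl_vals) >= 0)
        assert set(table.columns) == {"OVL", "AUC", "modality_group", "label"}

    def test_arrow_plot_file_and_point_counts(self, small_sim_results, tmp_path):
        res = small_sim_results
        sel = res.select(SelectionThresholds.simulated())
        path = tmp_path / "arrow.png"
        ax = res.plot(path)
        assert path.exists() and path.stat().st_size > 0
        # one point per scored gene, split across the label layers
        import matplotlib.pyplot as plt

        n_points = sum(len(c.get_offsets()) for c in ax.collections)
        assert n_points == (sel["status"] == "ok").sum()
        plt.close("all")

    def test_arrow_plot_empty_stats(self, tmp_path):
        import pandas as pd

        path = tmp_path / "empty.svg"
        arrow_plot(pd.DataFrame(columns=["ovl", "auc"]), path, SelectionThresholds())
        assert path.exists() and path.stat().st_size > 0
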