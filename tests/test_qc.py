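import numpy as np
import pandas as pd
import pytest

from triheme import (
    CellTable,
    GeneCountMatrix,
    ValidationError,
    aggregate_to_genes,
    dedup_replicates,
    filter_cells,
    filter_dropout_genes,
    flag_batch_genes,
    log_normalize,
)


def _cells(rows):
    df = pd.DataFrame(rows).set_index("cell_id")
    return CellTable(df)


def _gcm(cell_ids, n_genes=3):
    counts = np.ones((len(cell_ids), n_genes))
    return GeneCountMatrix(cell_ids, [f"g{i}" for i in range(n_genes)], counts)


class TestFilterCells:
    def test_each_rule_and_boundary_convention(self):
        cells = _cells([
            {"cell_id": "low", "n_genes_detected": 1999, "pct_mito": 5.0, "pct_hemoglobin": 0.0},
            {"cell_id": "edge", "n_genes_detected": 2000, "pct_mito": 15.0, "pct_hemoglobin": 10.0},
            {"cell_id": "mito", "n_genes_detected": 5000, "pct_mito": 15.1, "pct_hemoglobin": 0.0},
            {"cell_id": "hb", "n_genes_detected": 5000, "pct_mito": 1.0, "pct_hemoglobin": 10.1},
        ])
        rep = filter_cells(_gcm(list(cells.df.index)), cells)
        status = rep.cell_status
        assert not status.loc["low", "passed"] and status.loc["low", "rules"] == "min_genes"
        assert status.loc["edge", "passed"]  # boundary values pass
        assert status.loc["mito", "rules"] == "max_mito"
        assert status.loc["hb", "rules"] == "max_hb"
        assert rep.retained_cells == ["edge"]

    def test_metrics_computed_from_gene_lists_when_missing(self):
        counts = np.array([[80.0, 20.0, 0.0], [50.0, 0.0, 50.0]])
        gcm = GeneCountMatrix(["c1", "c2"], ["mt1", "hb1", "g1"], counts)
        cells = CellTable(pd.DataFrame({"population": ["A", "A"]},
                                       index=pd.Index(["c1", "c2"], name="cell_id")))
        rep = filter_cells(gcm, cells, min_genes=1, mito_genes=["mt1"], hb_genes=["hb1"])
        # c1: 80% mito -> fail; c2: 50% mito, 0% hb -> fail mito as well
        assert not rep.cell_status["passed"].any()
        rep2 = filter_cells(gcm, cells, min_genes=1, max_mito=90, mito_genes=["mt1"], hb_genes=["hb1"])
        assert rep2.cell_status.loc["c2", "passed"]

    def test_missing_metrics_without_gene_lists_rejected(self):
        cells = CellTable(pd.DataFrame({"population": ["A"]},
                                       index=pd.Index(["c1"], name="cell_id")))
        with pytest.raises(ValidationError):
            filter_cells(_gcm(["c1"]), cells)

    def test_planted_violations_found_exactly(self, planted_qc_sim):
        sim = planted_qc_sim
        gcm = aggregate_to_genes(sim.icm, sim.gene_model)
        rep = filter_cells(gcm, sim.cells)
        failed = set(rep.cell_status.index[~rep.cell_status["passed"]])
        planted = set(sim.cell_truth.index[sim.cell_truth["violation"] != "replicate"])
        assert failed == planted
        by_rule = sim.cell_truth["violation"].value_counts()
        assert by_rule["max_mito"] == 5
        got_mito = set(rep.cell_status.index[rep.cell_status["rules"] == "max_mito"])
        assert got_mito == set(sim.cell_truth.index[sim.cell_truth["violation"] == "max_mito"])

    def test_idempotent(self, planted_qc_sim):
        sim = planted_qc_sim
        gcm = aggregate_to_genes(sim.icm, sim.gene_model)
        rep = filter_cells(gcm, sim.cells)
        again = filter_cells(gcm.subset_cells(rep.retained_cells),
                             sim.cells.subset(rep.retained_cells))
        assert again.retained_cells == rep.retained_cells


class TestDedupReplicates:
    def test_keeps_highest_gene_count_and_breaks_ties_lexicographically(self):
        cells = _cells([
            {"cell_id": "cellA", "n_genes_detected": 4000, "replicate_group": "r1"},
            {"cell_id": "cellB", "n_genes_detected": 3500, "replicate_group": "r1"},
            {"cell_id": "cellD", "n_genes_detected": 4000, "replicate_group": "r2"},
            {"cell_id": "cellC", "n_genes_detected": 4000, "replicate_group": "r2"},
            {"cell_id": "solo", "n_genes_detected": 3000, "replicate_group": "r3"},
            {"cell_id": "free", "n_genes_detected": 2500, "replicate_group": None},
        ])
        rep = dedup_replicates(_gcm(list(cells.df.index)), cells)
        assert set(rep.removed_replicates) == {"cellB", "cellD"}
        assert "solo" in rep.retained_cells and "free" in rep.retained_cells

    def test_planted_replicates_removed(self, planted_qc_sim):
        sim = planted_qc_sim
        gcm = aggregate_to_genes(sim.icm, sim.gene_model)
        rep = dedup_replicates(gcm, sim.cells)
        twins = set(sim.cell_truth.index[sim.cell_truth["violation"] == "replicate"])
        assert set(rep.removed_replicates) == twins
        assert len(twins) == 3


class TestDropoutFilter:
    def test_strict_boundary_at_90_percent(self):
        counts = np.zeros((100, 3))
        counts[:9, 0] = 1  # 91% dropout -> excluded
        counts[:10, 1] = 1  # 90% dropout -> retained
        # column 2 all zero -> excluded
        gcm = GeneCountMatrix([f"c{i}" for i in range(100)], ["g91", "g90", "g0"], counts)
        rep = filter_dropout_genes(gcm, [gcm.cell_ids])
        assert set(rep.excluded_genes.index) == {"g91", "g0"}

    def test_empty_group_rejected(self):
        gcm = _gcm(["c1"])
        with pytest.raises(ValidationError):
            filter_dropout_genes(gcm, [[]])


class TestBatchGenes:
    def _bridge(self, det1, det2, n=40):
        """One gene detected in det1 of batch1 cells and det2 of batch2 cells."""
        counts = np.zeros((2 * n, 2))
        counts[: int(det1 * n), 0] = 5
        counts[n : n + int(det2 * n), 0] = 5
        counts[:, 1] = 10  # stable reference gene keeps totals positive
        gcm = GeneCountMatrix([f"c{i}" for i in range(2 * n)], ["gx", "ref"], counts)
        gcm = log_normalize(gcm)
        cells = CellTable(pd.DataFrame({
            "population": ["ENDO"] * 2 * n,
            "batch": ["b1"] * n + ["b2"] * n,
        }, index=pd.Index(gcm.cell_ids, name="cell_id")))
        return gcm, cells

    def test_detection_rate_rule(self):
        gcm, cells = self._bridge(0.9, 0.3)
        rep = flag_batch_genes(gcm, cells, "ENDO")
        assert "gx" in rep.excluded_genes.index
        assert "batch-detection" in rep.excluded_genes.loc["gx", "reason"]

    def test_moderate_detection_difference_not_flagged(self):
        gcm, cells = self._bridge(0.55, 0.40)
        rep = flag_batch_genes(gcm, cells, "ENDO")
        assert "gx" not in rep.excluded_genes.index

    def test_single_batch_bridge_rejected(self):
        gcm, cells = self._bridge(0.9, 0.3)
        cells.df["batch"] = "b1"
        with pytest.raises(ValidationError):
            flag_batch_genes(gcm, cells, "ENDO")

    def test_planted_batch_genes_flagged(self, default_sim, norm_gcm):
        rep = flag_batch_genes(norm_gcm, default_sim.cells, "ENDO_AGM")
        flagged = set(rep.excluded_genes.index)
        planted = set(default_sim.genes_of_class("batch"))
        assert planted <= flagged
        assert len(flagged - planted) <= 2
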