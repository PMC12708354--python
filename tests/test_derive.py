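import numpy as np
import pandas as pd
import pytest

from triheme import (
    GeneCountMatrix,
    ValidationError,
    classify_to_reference,
    derive_fate_signatures,
    derive_shared_profile,
    filter_factors,
    flag_batch_genes,
    interhe_deg,
    label_fraction_table,
)
from .conftest import make_gcm


def _nine_population_gcm(gene_specs, n=12, high=40, low=1):
    """gene_specs: gene -> set of populations where the gene is high."""
    pops = ["ENDO_AGM", "ENDO_YS", "HE_AGM", "HE_YSA", "HE_YSP",
            "PROG_P1", "PROG_P2", "EMP", "LMP"]
    values = {}
    for gene, high_pops in gene_specs.items():
        values[gene] = {p: [high if p in high_pops else low] * n for p in pops}
    # a flat housekeeping gene keeps the BH family honest
    values["hk"] = {p: [10] * n for p in pops}
    return make_gcm(values, {p: n for p in pops})


HES = {"HE_AGM", "HE_YSA", "HE_YSP"}
ENDS = {"ENDO_AGM", "ENDO_YS"}
HEM = {"EMP", "LMP"}
PROG = {"PROG_P1", "PROG_P2"}


class TestSharedProfile:
    def test_arm_assignment_rules(self):
        gcm, cells = _nine_population_gcm({
            "he_only": HES,                          # up vs both ends everywhere
            "endo_gene": ENDS | HES,                 # shut down toward blood
            "hem_gene": HES | HEM | PROG,            # activated in HE, stays on
            "two_of_three": {"HE_AGM", "HE_YSA"},    # fails the all-HE rule
        })
        profile = derive_shared_profile(gcm, cells)
        assert profile.table.loc["he_only", "arm"] == "HE-restricted"
        assert profile.table.loc["endo_gene", "arm"] == "endothelial-biased"
        assert profile.table.loc["hem_gene", "arm"] == "hematopoietic-biased"
        assert "two_of_three" not in profile.table.index
        assert "hk" not in profile.table.index

    def test_pct_rule_excludes_sparsely_expressed_gene(self):
        gcm, cells = _nine_population_gcm({"he_only": HES})
        # silence the gene in most HE_YSP cells: expressed in only 25% of them
        col = list(gcm.gene_ids).index("he_only")
        ysp_rows = gcm.cell_index(cells.cells_of("HE_YSP"))
        gcm.counts[ysp_rows[3:], col] = 0
        gcm.normalized[ysp_rows[3:], col] = 0
        profile = derive_shared_profile(gcm, cells)
        assert "he_only" not in profile.table.index

    def test_missing_population_rejected(self):
        gcm, cells = make_gcm({"g": {"HE_AGM": [1] * 3}}, {"HE_AGM": 3})
        with pytest.raises(ValidationError, match="missing population"):
            derive_shared_profile(gcm, cells)

    def test_cell_order_invariance(self):
        gcm, cells = _nine_population_gcm({"he_only": HES, "endo_gene": ENDS | HES})
        perm = np.random.default_rng(0).permutation(gcm.n_cells)
        shuffled = GeneCountMatrix([gcm.cell_ids[i] for i in perm], list(gcm.gene_ids),
                                   gcm.counts[perm], gcm.normalized[perm])
        p1 = derive_shared_profile(gcm, cells)
        p2 = derive_shared_profile(shuffled, cells)
        assert p1.table["arm"].to_dict() == p2.table["arm"].to_dict()

    def test_restricted_subset_of_profile_and_arms_partition(self, default_sim, norm_gcm):
        flagged = set(flag_batch_genes(norm_gcm, default_sim.cells, "ENDO_AGM").excluded_genes.index)
        gcm = norm_gcm.subset_genes([g for g in norm_gcm.gene_ids if g not in flagged])
        profile = derive_shared_profile(gcm, default_sim.cells)
        assert set(profile.he_restricted) <= set(profile.genes)
        assert set(profile.table["arm"]) <= {"HE-restricted", "endothelial-biased",
                                             "hematopoietic-biased"}
        assert sorted(profile.he_restricted) == sorted(default_sim.genes_of_class("he_restricted"))


class TestInterHE:
    def test_marker_lands_in_single_population_region(self):
        gcm, cells = _nine_population_gcm({"agm_marker": {"HE_AGM"}})
        res = interhe_deg(gcm, cells)
        assert "agm_marker" in res["up_sets"]["HE_AGM"]
        assert res["venn"]["100"] >= 1 and res["venn"]["111"] == 0

    def test_pct_rule_blocks_sparse_marker(self):
        gcm, cells = _nine_population_gcm({"agm_marker": {"HE_AGM"}})
        col = list(gcm.gene_ids).index("agm_marker")
        agm_rows = gcm.cell_index(cells.cells_of("HE_AGM"))
        gcm.counts[agm_rows[5:], col] = 0  # expressed in only 5/12 < 50%
        gcm.normalized[agm_rows[5:], col] = 0
        res = interhe_deg(gcm, cells)
        assert "agm_marker" not in res["up_sets"]["HE_AGM"]

    def test_null_data_gives_empty_up_sets(self):
        rng = np.random.default_rng(8)
        pops = {"HE_AGM": 30, "HE_YSA": 30, "HE_YSP": 30}
        values = {f"g{i}": {p: rng.poisson(20, 30).tolist() for p in pops} for i in range(100)}
        gcm, cells = make_gcm(values, pops)
        res = interhe_deg(gcm, cells)
        assert all(len(s) == 0 for s in res["up_sets"].values())


class TestFateSignatures:
    def test_rule_and_exclusions(self):
        gcm, cells = _nine_population_gcm({
            "emp_like": {"EMP", "PROG_P2"},
            "lmp_like": {"LMP", "PROG_P1"},
            "emp_only": {"EMP"},  # null in the progenitor contrast -> excluded
        })
        fate = derive_fate_signatures(gcm, cells)
        assert fate.emp_fate == ["emp_like"]
        assert fate.lmp_fate == ["lmp_like"]
        assert "emp_only" not in fate.emp_fate

    def test_exact_recovery_of_planted_sets(self, default_sim, norm_gcm):
        fate = derive_fate_signatures(norm_gcm, default_sim.cells)
        assert sorted(fate.emp_fate) == sorted(default_sim.genes_of_class("emp_fate"))
        assert sorted(fate.lmp_fate) == sorted(default_sim.genes_of_class("lmp_fate"))

    def test_label_permuted_data_yields_empty_signatures(self):
        rng = np.random.default_rng(9)
        pops = {"EMP": 30, "LMP": 30, "PROG_P1": 30, "PROG_P2": 30}
        values = {f"g{i}": {p: rng.poisson(15, 30).tolist() for p in pops} for i in range(200)}
        gcm, cells = make_gcm(values, pops)
        fate = derive_fate_signatures(gcm, cells)
        assert fate.emp_fate == [] and fate.lmp_fate == []


class TestKNNClassifier:
    def _clusters(self, rng, n=40, shift=8.0, n_genes=30):
        a = rng.normal(0, 1, size=(n, n_genes))
        b = rng.normal(shift, 1, size=(n, n_genes))
        x = np.abs(np.vstack([a, b]))
        ids = [f"r{i}" for i in range(2 * n)]
        gcm = GeneCountMatrix(ids, [f"g{i}" for i in range(n_genes)], x, x.copy())
        labels = {c: ("a1" if i < n else "b1") for i, c in enumerate(ids)}
        return gcm, labels

    def test_query_identical_to_reference_cell_gets_its_cluster(self):
        rng = np.random.default_rng(10)
        ref, labels = self._clusters(rng)
        q = GeneCountMatrix(["q"], list(ref.gene_ids), ref.counts[:1].copy(),
                            ref.normalized[:1].copy())
        out = classify_to_reference(ref, labels, q, k=5)
        assert out.loc["q", "label"] == "a1"

    def test_separated_clusters_classified_perfectly(self):
        rng = np.random.default_rng(11)
        ref, labels = self._clusters(rng)
        qa = np.abs(rng.normal(0, 1, size=(15, 30)))
        qb = np.abs(rng.normal(8.0, 1, size=(15, 30)))
        q = GeneCountMatrix([f"q{i}" for i in range(30)],
                            list(ref.gene_ids), np.vstack([qa, qb]),
                            np.vstack([qa, qb]))
        out = classify_to_reference(ref, labels, q, k=10)
        assert list(out["label"]) == ["a1"] * 15 + ["b1"] * 15
        frac = label_fraction_table(out, {c: ("A" if c in [f"q{i}" for i in range(15)] else "B")
                                          for c in q.cell_ids})
        assert frac.loc["A", "a1"] == 100.0

    def test_invalid_k_rejected(self):
        rng = np.random.default_rng(12)
        ref, labels = self._clusters(rng, n=5)
        q = GeneCountMatrix(["q"], list(ref.gene_ids), ref.counts[:1], ref.normalized[:1])
        with pytest.raises(ValidationError):
            classify_to_reference(ref, labels, q, k=0)
        with pytest.raises(ValidationError):
            classify_to_reference(ref, labels, q, k=1000)


class TestFilterFactors:
    def test_order_preserving_intersection(self):
        assert filter_factors(["A", "B", "C"], ["B", "C", "D"]) == ["B", "C"]

    def test_disjoint_sets_give_empty(self):
        assert filter_factors(["A"], ["B"]) == []

    def test_duplicates_removed_and_empty_factor_list_rejected(self):
        assert filter_factors(["A", "A", "B"], ["A", "A"]) == ["A"]
        with pytest.raises(ValidationError):
            filter_factors(["A"], [])
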