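import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triheme import (
    CellTable,
    GeneCountMatrix,
    Signature,
    ValidationError,
    compare_scores,
    score_cell,
    score_matrix,
)


def brute_force_score(expr, universe, genes, r_max):
    """Independent direct evaluation of the capped-U formula (sorting-based)."""
    order = sorted(range(len(expr)), key=lambda i: -expr[i])
    # average ranks for ties
    ranks = np.empty(len(expr))
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and expr[order[j + 1]] == expr[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    ranks = np.minimum(ranks, r_max + 1)
    idx = {g: i for i, g in enumerate(universe)}
    n = len(genes)
    u = sum(ranks[idx[g]] for g in genes) - n * (n + 1) / 2
    return float(min(max(1 - u / (n * r_max), 0.0), 1.0))


@pytest.fixture
def universe():
    return [f"g{i}" for i in range(2000)]


@pytest.fixture
def descending_expr(universe):
    # g0 has the highest expression, g1999 the lowest (all distinct, nonzero tail)
    return np.linspace(2000, 1, len(universe))


class TestScoreFormula:
    def test_top_ranked_signature_scores_one(self, universe, descending_expr):
        sig = Signature("top", ["g0", "g1"])
        assert score_cell(descending_expr, universe, sig) == 1.0

    def test_beyond_rmax_scores_zero(self, universe, descending_expr):
        sig = Signature("bottom", ["g1999"])
        assert score_cell(descending_expr, universe, sig) == 0.0

    def test_midpoint_rank_gives_half(self, universe, descending_expr):
        sig = Signature("mid", ["g750"])  # rank 751
        assert score_cell(descending_expr, universe, sig, r_max=1500) == pytest.approx(0.5)

    def test_oversized_signature_rejected(self, universe, descending_expr):
        sig = Signature("big", [f"g{i}" for i in range(20)])
        with pytest.raises(ValidationError):
            score_cell(descending_expr, universe, sig, r_max=10)

    def test_absent_genes_warn_and_all_absent_errors(self, universe, descending_expr):
        with pytest.warns(UserWarning, match="absent"):
            s = score_cell(descending_expr, universe, Signature("x", ["g0", "nope"]))
        assert s == 1.0
        with pytest.raises(ValidationError):
            score_cell(descending_expr, universe, Signature("x", ["nope"]))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        universe = [f"g{i}" for i in range(120)]
        for _ in range(300):
            expr = np.round(rng.exponential(2.0, size=120), 2)  # plenty of ties
            n_sig = rng.integers(1, 12)
            genes = list(rng.choice(universe, size=n_sig, replace=False))
            r_max = int(rng.integers(max(n_sig, 10), 120))
            got = score_cell(expr, universe, Signature("s", genes), r_max=r_max)
            want = brute_force_score(expr, universe, genes, r_max)
            assert got == pytest.approx(want, abs=1e-12)


class TestScoreMatrix:
    def _gcm(self, expr, universe):
        return GeneCountMatrix([f"c{i}" for i in range(expr.shape[0])], universe,
                               expr, expr.copy())

    def test_shape_and_gene_order_invariance(self, universe):
        rng = np.random.default_rng(0)
        expr = rng.random((2, len(universe)))
        sigs = [Signature("a", ["g3", "g7"]), Signature("b", ["g10"])]
        scores = score_matrix(self._gcm(expr, universe), sigs)
        assert scores.shape == (2, 2)
        perm = rng.permutation(len(universe))
        shuffled = self._gcm(expr[:, perm], [universe[i] for i in perm])
        scores_perm = score_matrix(shuffled, sigs)
        assert np.allclose(scores.to_numpy(), scores_perm.to_numpy())

    def test_invariant_to_monotone_transform(self, universe):
        rng = np.random.default_rng(1)
        expr = rng.random((3, len(universe)))
        sigs = [Signature("a", ["g5", "g50", "g500"])]
        s1 = score_matrix(self._gcm(expr, universe), sigs)
        s2 = score_matrix(self._gcm(np.exp(5 * expr), universe), sigs)
        assert np.allclose(s1.to_numpy(), s2.to_numpy())

    def test_planted_population_separation(self, default_sim, norm_gcm):
        sig = Signature("he", default_sim.genes_of_class("he_restricted"))
        scores = score_matrix(norm_gcm, [sig])
        pops = default_sim.cells.df["population"]
        he = scores.loc[pops.isin(["HE_AGM", "HE_YSA", "HE_YSP"]).to_numpy(), "he"]
        endo = scores.loc[(pops == "ENDO_AGM").to_numpy(), "he"]
        assert (he.to_numpy() > endo.median()).mean() >= 0.95


class TestCompareScores:
    def _table(self, scores_by_pop):
        rows, pops = [], []
        for pop, vals in scores_by_pop.items():
            for i, v in enumerate(vals):
                rows.append((f"{pop}_{i}", v))
                pops.append(pop)
        scores = pd.DataFrame({"sig": [v for _, v in rows]},
                              index=pd.Index([c for c, _ in rows], name="cell_id"))
        cells = CellTable(pd.DataFrame({"population": pops}, index=scores.index))
        return scores, cells

    def test_identical_distributions_give_p_one(self):
        scores, cells = self._table({"A": [0.2] * 10, "B": [0.2] * 10})
        out = compare_scores(scores, cells, [("A", "B")])
        assert out["p"].iloc[0] == 1.0

    def test_rows_and_adjustment(self):
        rng = np.random.default_rng(2)
        scores, cells = self._table({p: rng.random(8) for p in ("A", "B", "C")})
        scores["sig2"] = rng.random(len(scores))
        out = compare_scores(scores, cells, [("A", "B"), ("A", "C"), ("B", "C")])
        assert len(out) == 6
        assert (out["padj"] >= out["p"] - 1e-15).all()

    def test_shifted_scores_detected(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0.4, 0.05, size=50).clip(0, 1)
        scores, cells = self._table({"A": base + 0.2, "B": base})
        out = compare_scores(scores, cells, [("A", "B")])
        assert out["padj"].iloc[0] < 0.05

    def test_unknown_population_rejected(self):
        scores, cells = self._table({"A": [0.1] * 3, "B": [0.2] * 3})
        with pytest.raises(ValidationError):
            compare_scores(scores, cells, [("A", "Z")])
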