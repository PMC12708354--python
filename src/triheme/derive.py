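"""Set-construction procedures on top of the DE engine.

* A shared HE expression profile: genes differentially expressed, in every
  one of the three HE populations, against the endothelial and/or
  hematopoietic ends of the endothelial-to-hematopoietic trajectory, with
  arm labels (endothelial-biased / hematopoietic-biased / HE-restricted).
* Pairwise inter-HE DEG sets with a Venn partition of per-population "up"
  sets.
* EMP-fate / LMP-fate signatures by intersecting two independent contrasts
  (EMP vs LMP, and the early progenitor clusters p2 vs p1; p2 resembles
  EMP and p1 resembles LMP).
* k-nearest-neighbour assignment of query cells to reference clusters in
  the reference's principal-component space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .de import ContrastSpec, downsample_equal, run_de
from .types import (
    CellTable,
    ENDOTHELIAL_END,
    GeneCountMatrix,
    HE_POPULATIONS,
    HEMATOPOIETIC_END,
    ValidationError,
)


@dataclass
class SharedProfile:
    """Shared HE gene set with arm labels and per-HE contrast evidence."""

    table: pd.DataFrame  # index gene: arm + per-HE log2FC/padj columns
    evidence: dict  # (he, end) -> DE result frame

    @property
    def genes(self) -> list:
        return list(self.table.index)

    def arm(self, name: str) -> list:
        return list(self.table.index[self.table["arm"] == name])

    @property
    def he_restricted(self) -> list:
        return self.arm("HE-restricted")


def _require_populations(cells: CellTable, pops: Sequence) -> None:
    have = set(cells.df["population"])
    missing = [p for p in pops if p not in have]
    if missing:
        raise ValidationError(f"missing population(s): {missing}")


def derive_shared_profile(
    gcm: GeneCountMatrix,
    cells: CellTable,
    lfc: float = 1.0,
    fdr: float = 0.05,
    pct: float = 0.33,
    max_dropout: float = 0.90,
    require_all_hes: bool = True,
) -> SharedProfile:
    """Shared HE profile across the three HE populations.

    Per HE, two contrasts are run: HE vs its nearest endothelium and HE vs
    the pooled EMP+LMP hematopoietic end.  A gene enters the profile iff it
    is expressed in >= ``pct`` of each HE's cells and passes |log2FC| > lfc
    with padj < fdr in at least one end-contrast in every HE (or, with
    ``require_all_hes=False``, in any HE), with a consistent direction
    pattern across HEs.  Arms: HE-restricted genes are up versus BOTH ends
    in all three HEs; otherwise a gene biased toward the endothelial end
    (down in HE vs endothelium, or up vs the hematopoietic end) is
    endothelial-biased, and a gene biased toward the hematopoietic end (up
    vs endothelium, or down vs the hematopoietic end) is
    hematopoietic-biased.
    """
    _require_populations(cells, list(HE_POPULATIONS) + sorted(set(ENDOTHELIAL_END.values())) + list(HEMATOPOIETIC_END))
    hem_cells = [c for p in HEMATOPOIETIC_END for c in cells.cells_of(p)]

    evidence: dict = {}
    for he in HE_POPULATIONS:
        he_cells = cells.cells_of(he)
        endo_cells = cells.cells_of(ENDOTHELIAL_END[he])
        for end, other in (("endo", endo_cells), ("hem", hem_cells)):
            spec = ContrastSpec(he_cells, other, name_a=he, name_b=end, lfc=lfc, fdr=fdr)
            evidence[(he, end)] = run_de(gcm, spec, max_dropout=max_dropout)

    genes = sorted(set.intersection(*(set(df.index) for df in evidence.values())))
    rows = []
    for gene in genes:
        passes, signs = [], []
        pct_ok = True
        for he in HE_POPULATIONS:
            e = evidence[(he, "endo")].loc[gene]
            h = evidence[(he, "hem")].loc[gene]
            if min(e["pct_expr_a"], h["pct_expr_a"]) < pct:
                pct_ok = False
                break
            pass_e = (abs(e["log2FC"]) > lfc) and (e["padj"] < fdr)
            pass_h = (abs(h["log2FC"]) > lfc) and (h["padj"] < fdr)
            passes.append(pass_e or pass_h)
            signs.append((np.sign(e["log2FC"]) if pass_e else 0, np.sign(h["log2FC"]) if pass_h else 0))
        if not pct_ok:
            continue
        enough = all(passes) if require_all_hes else any(passes)
        if not enough:
            continue
        # direction consistency: no end-contrast may pass in opposite directions across HEs
        se = {s for s, _ in signs if s != 0}
        sh = {s for _, s in signs if s != 0}
        if len(se) > 1 or len(sh) > 1:
            continue
        up_endo = se == {1.0}
        down_endo = se == {-1.0}
        up_hem = sh == {1.0}
        down_hem = sh == {-1.0}
        if up_endo and up_hem and all(s == (1, 1) for s in signs):
            arm = "HE-restricted"
        elif down_endo or up_hem:
            arm = "endothelial-biased"
        elif up_endo or down_hem:
            arm = "hematopoietic-biased"
        else:
            continue
        rows.append(
            {
                "gene": gene,
                "arm": arm,
                **{f"log2FC_{he}_vs_endo": evidence[(he, "endo")].loc[gene, "log2FC"] for he in HE_POPULATIONS},
                **{f"log2FC_{he}_vs_hem": evidence[(he, "hem")].loc[gene, "log2FC"] for he in HE_POPULATIONS},
            }
        )
    table = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(columns=["arm"])
    return SharedProfile(table, evidence)


def interhe_deg(
    gcm: GeneCountMatrix,
    cells: CellTable,
    lfc: float = 1.5,
    fdr: float = 0.05,
    pct: float = 0.50,
    max_dropout: float = 0.90,
) -> dict:
    """Pairwise inter-HE DE plus per-population 'up' sets and Venn counts.

    A gene is in a population's up-set when it is upregulated (log2FC > lfc,
    padj < fdr, expressed in > pct of the upregulated population's cells)
    versus at least one other HE population.
    """
    _require_populations(cells, HE_POPULATIONS)
    results: dict = {}
    up_sets: dict = {he: set() for he in HE_POPULATIONS}
    for he_a, he_b in combinations(HE_POPULATIONS, 2):
        spec = ContrastSpec(cells.cells_of(he_a), cells.cells_of(he_b),
                            name_a=he_a, name_b=he_b, lfc=lfc, fdr=fdr, pct=pct)
        res = run_de(gcm, spec, max_dropout=max_dropout)
        results[(he_a, he_b)] = res
        up_sets[he_a] |= set(res.index[res["up_in_a"]])
        up_sets[he_b] |= set(res.index[res["up_in_b"]])
    venn = _venn3_counts(*(up_sets[he] for he in HE_POPULATIONS))
    return {"pairwise": results, "up_sets": up_sets, "venn": venn}


def _venn3_counts(a: set, b: set, c: set) -> dict:
    return {
        "100": len(a - b - c),
        "010": len(b - a - c),
        "001": len(c - a - b),
        "110": len((a & b) - c),
        "101": len((a & c) - b),
        "011": len((b & c) - a),
        "111": len(a & b & c),
    }


@dataclass
class FateSignature:
    """Prospective EMP-fate and LMP-fate gene signatures with provenance."""

    emp_fate: list
    lmp_fate: list
    provenance: dict  # contrast name -> DE frame

    def __post_init__(self) -> None:
        if set(self.emp_fate) & set(self.lmp_fate):
            raise ValidationError("EMP-fate and LMP-fate signatures must be disjoint")


def derive_fate_signatures(
    gcm: GeneCountMatrix,
    cells: CellTable,
    padj: float = 0.05,
    max_dropout: float = 0.90,
) -> FateSignature:
    """Fate signatures from the intersection of two contrasts at padj < 0.05.

    EMP-fate genes are up in EMP (vs LMP) and up in progenitor cluster p2
    (vs p1); LMP-fate genes are up in LMP and up in p1.
    """
    _require_populations(cells, ("EMP", "LMP", "PROG_P1", "PROG_P2"))
    de_el = run_de(gcm, ContrastSpec(cells.cells_of("EMP"), cells.cells_of("LMP"),
                                     name_a="EMP", name_b="LMP"), max_dropout=max_dropout)
    de_p = run_de(gcm, ContrastSpec(cells.cells_of("PROG_P2"), cells.cells_of("PROG_P1"),
                                    name_a="PROG_P2", name_b="PROG_P1"), max_dropout=max_dropout)
    common = de_el.index.intersection(de_p.index)
    el, pr = de_el.loc[common], de_p.loc[common]
    emp = common[(el["log2FC"] > 0) & (el["padj"] < padj) & (pr["log2FC"] > 0) & (pr["padj"] < padj)]
    lmp = common[(el["log2FC"] < 0) & (el["padj"] < padj) & (pr["log2FC"] < 0) & (pr["padj"] < padj)]
    return FateSignature(sorted(emp), sorted(lmp), {"EMP_vs_LMP": de_el, "P2_vs_P1": de_p})


def classify_to_reference(
    ref_gcm: GeneCountMatrix,
    ref_labels: Mapping,
    query_gcm: GeneCountMatrix,
    k: int = 10,
    n_components: int = 50,
) -> pd.DataFrame:
    """Assign each query cell to a reference cluster by majority k-NN vote.

    PCA is fitted on the reference's normalized expression; queries are
    projected into that space and voted on by Euclidean k-NN.  Vote ties go
    to the label with the smallest summed distance.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > ref_gcm.n_cells:
        raise ValidationError(f"k={k} exceeds the {ref_gcm.n_cells}-cell reference")
    if list(ref_gcm.gene_ids) != list(query_gcm.gene_ids):
        raise ValidationError("reference and query must share the same gene universe")
    x_ref = ref_gcm.normalized if ref_gcm.normalized is not None else ref_gcm.counts
    x_query = query_gcm.normalized if query_gcm.normalized is not None else query_gcm.counts
    n_comp = min(n_components, ref_gcm.n_cells - 1, len(ref_gcm.gene_ids))
    mu, sd = x_ref.mean(axis=0), x_ref.std(axis=0)
    sd[sd == 0] = 1.0
    pca = PCA(n_components=n_comp, random_state=0)
    z_ref = pca.fit_transform((x_ref - mu) / sd)
    z_query = pca.transform((x_query - mu) / sd)
    nn = NearestNeighbors(n_neighbors=k).fit(z_ref)
    dist, idx = nn.kneighbors(z_query)
    labels = np.asarray([ref_labels[c] for c in ref_gcm.cell_ids], dtype=object)
    assigned = []
    for d_row, i_row in zip(dist, idx):
        votes: dict = {}
        for d, i in zip(d_row, i_row):
            lab = labels[i]
            cnt, dsum = votes.get(lab, (0, 0.0))
            votes[lab] = (cnt + 1, dsum + d)
        best = min(votes.items(), key=lambda kv: (-kv[1][0], kv[1][1]))
        assigned.append(best[0])
    return pd.DataFrame({"label": assigned}, index=pd.Index(query_gcm.cell_ids, name="cell_id"))


def label_fraction_table(assignments: pd.DataFrame, query_populations: Mapping) -> pd.DataFrame:
    """Percent of each query population assigned to each reference cluster."""
    df = assignments.copy()
    df["population"] = [query_populations[c] for c in df.index]
    counts = df.groupby(["population", "label"]).size().unstack(fill_value=0)
    return 100.0 * counts.div(counts.sum(axis=1), axis=0)


def filter_factors(gene_set: Sequence, factor_list: Sequence) -> list:
    """Order-preserving intersection with a curated factor list, de-duplicated."""
    factors = set(factor_list)
    if not factors:
        raise ValidationError("factor list is empty")
    return [g for g in dict.fromkeys(gene_set) if g in factors]
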