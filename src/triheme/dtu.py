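"""Differential transcript usage: isoform fractions, dIF, and switch calls.

Pooled isoform fraction of isoform i in a group of cells is
IF_i = sum_cells c_i / sum_cells (gene total), computed over qualifying
cells (gene total >= min_total).  dIF = IF_A - IF_B.  Significance per
isoform comes from a two-sided label-permutation test on the pooled dIF
(add-one corrected, p = (b + 1) / (n_perm + 1)), BH-adjusted across every
tested isoform; a gene is a significant switch when any of its isoforms
has |dIF| > dif_min and padj < fdr.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .de import bh_adjust
from .types import CellTable, GeneModel, IsoformCountMatrix, ValidationError


@dataclass
class IsoformFractionTable:
    """Per-group isoform fractions plus the qualifying per-cell counts."""

    group: str
    pooled: pd.DataFrame  # index isoform_id: gene_id, IF, n_qualifying_cells
    cell_counts: dict  # gene_id -> (cell_ids, counts ndarray cells x k, isoform_ids)

    def gene_if(self, gene: str) -> Optional[np.ndarray]:
        sub = self.pooled[self.pooled["gene_id"] == gene]
        return sub["IF"].to_numpy() if len(sub) else None


def isoform_fractions(
    icm: IsoformCountMatrix,
    gm: GeneModel,
    cells: CellTable,
    group,
    min_total: int = 10,
) -> IsoformFractionTable:
    """Pooled and per-cell isoform fractions for one cell group.

    ``group`` is a population label or an explicit cell-id sequence.  Genes
    never expressed (no qualifying cell) get NaN pooled fractions.
    """
    if isinstance(group, str):
        name, members = group, cells.cells_of(group)
    else:
        name, members = "custom", list(group)
    if not members:
        raise ValidationError(f"group {name!r} is empty")
    rows = [i for i, c in enumerate(icm.cell_ids) if c in set(members)]
    sub = icm.counts[rows]
    cell_ids = [icm.cell_ids[i] for i in rows]

    by_gene: dict = {}
    for j, iso in enumerate(icm.isoform_ids):
        gene = gm.isoform_to_gene.get(iso)
        if gene is None:
            raise ValidationError(f"isoform {iso!r} absent from gene model")
        by_gene.setdefault(gene, ([], []))
        by_gene[gene][0].append(j)
        by_gene[gene][1].append(iso)

    pooled_rows = []
    cell_counts: dict = {}
    for gene, (cols, isos) in by_gene.items():
        c = sub[:, cols]
        totals = c.sum(axis=1)
        qual = totals >= min_total
        n_qual = int(qual.sum())
        if n_qual:
            pooled_tot = c[qual].sum()
            ifs = c[qual].sum(axis=0) / pooled_tot
        else:
            ifs = np.full(len(cols), np.nan)
        for iso, f in zip(isos, ifs):
            pooled_rows.append((iso, gene, f, n_qual))
        cell_counts[gene] = ([cid for cid, q in zip(cell_ids, qual) if q], c[qual], isos)
    pooled = pd.DataFrame(pooled_rows, columns=["isoform_id", "gene_id", "IF", "n_qualifying_cells"])
    pooled = pooled.set_index("isoform_id")
    return IsoformFractionTable(name, pooled, cell_counts)


def _pooled_dif(counts: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """Pooled IF difference (A - B) for one gene's qualifying cells."""
    a = counts[is_a].sum(axis=0)
    b = counts[~is_a].sum(axis=0)
    return a / a.sum() - b / b.sum()


@dataclass
class DTUResult:
    """Per-isoform dIF table and per-gene switch calls for one group pair."""

    isoforms: pd.DataFrame  # index isoform_id: gene_id, dIF, p, padj, significant
    genes: pd.DataFrame  # index gene_id: significant, n_cells_a, n_cells_b
    group_a: str
    group_b: str
    skipped_genes: list

    @property
    def significant_genes(self) -> list:
        return list(self.genes.index[self.genes["significant"]])


def dtu_test(
    ift_a: IsoformFractionTable,
    ift_b: IsoformFractionTable,
    dif_min: float = 0.1,
    fdr: float = 0.05,
    min_if_cells: int = 10,
    n_perm: int = 1000,
    seed: int = 0,
) -> DTUResult:
    """Label-permutation DTU test between two isoform-fraction tables."""
    rng = np.random.default_rng(seed)
    iso_rows = []
    gene_rows = []
    skipped = []
    genes = sorted(set(ift_a.cell_counts) & set(ift_b.cell_counts))
    for gene in genes:
        cells_a, counts_a, isos = ift_a.cell_counts[gene]
        cells_b, counts_b, isos_b = ift_b.cell_counts[gene]
        if isos != isos_b:
            raise ValidationError(f"isoform sets differ between groups for {gene!r}")
        n_a, n_b = len(cells_a), len(cells_b)
        if n_a < min_if_cells or n_b < min_if_cells:
            skipped.append(gene)
            continue
        if len(isos) < 2:
            continue  # single-isoform gene: dIF identically 0
        counts = np.vstack([counts_a, counts_b])
        is_a = np.zeros(n_a + n_b, dtype=bool)
        is_a[:n_a] = True
        obs = _pooled_dif(counts, is_a)

        # vectorized permutations: one-hot group-A membership matrix
        n = n_a + n_b
        order = np.argsort(rng.random((n_perm, n)), axis=1)
        perm_a = np.zeros((n_perm, n), dtype=bool)
        perm_a[np.arange(n_perm)[:, None], order[:, :n_a]] = True
        sums_a = perm_a.astype(float) @ counts  # n_perm x k
        sums_b = counts.sum(axis=0) - sums_a
        with np.errstate(invalid="ignore"):
            dif_perm = sums_a / sums_a.sum(axis=1, keepdims=True) - sums_b / sums_b.sum(axis=1, keepdims=True)
        exceed = (np.abs(dif_perm) >= np.abs(obs)[None, :]).sum(axis=0)
        p = (exceed + 1.0) / (n_perm + 1.0)
        for iso, d, pv in zip(isos, obs, p):
            iso_rows.append((iso, gene, d, pv, n_a, n_b))
    iso_df = pd.DataFrame(iso_rows, columns=["isoform_id", "gene_id", "dIF", "p", "n_cells_a", "n_cells_b"])
    iso_df = iso_df.set_index("isoform_id")
    iso_df["padj"] = bh_adjust(iso_df["p"].to_numpy()) if len(iso_df) else []
    iso_df["significant"] = (iso_df["dIF"].abs() > dif_min) & (iso_df["padj"] < fdr)
    gene_df = (
        iso_df.groupby("gene_id")
        .agg(significant=("significant", "any"),
             max_abs_dIF=("dIF", lambda s: float(np.max(np.abs(s)))),
             n_cells_a=("n_cells_a", "first"),
             n_cells_b=("n_cells_b", "first"))
        if len(iso_df)
        else pd.DataFrame(columns=["significant", "max_abs_dIF", "n_cells_a", "n_cells_b"])
    )
    return DTUResult(iso_df, gene_df, ift_a.group, ift_b.group, skipped)


def intersect_isoform_results(
    entropy_sets: Mapping[str, set],
    dtu_sets: Mapping[str, set],
) -> dict:
    """Venn partition of entropy- and dIF-significant gene sets per comparison.

    Returns per-comparison counts (entropy_only, dif_only, both), the
    per-comparison union, and the overall union across comparisons.
    """
    if set(entropy_sets) != set(dtu_sets):
        raise ValidationError("entropy and dIF results cover different comparisons")
    out: dict = {"comparisons": {}, "union": set()}
    for comp in entropy_sets:
        e, d = set(entropy_sets[comp]), set(dtu_sets[comp])
        out["comparisons"][comp] = {
            "entropy_only": len(e - d),
            "dif_only": len(d - e),
            "both": len(e & d),
            "union": e | d,
        }
        out["union"] |= e | d
    return out
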