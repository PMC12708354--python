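"""Isoform-usage entropy and group-wise differential entropy.

For a gene with k annotated isoforms and per-cell isoform counts c_i, usage
proportions are Laplace-smoothed, p_i = (c_i + 1) / (sum c + k), and the
normalized Shannon entropy is H = -sum p_i log2 p_i / log2 k, in [0, 1].
High entropy means balanced usage of several isoforms; low entropy a single
dominant isoform.  Cells with gene total below ``min_total`` and genes with
k = 1 are undefined (missing).  Group differences are tested per gene with
a two-sample rank-sum test on per-cell entropies, BH-corrected, and called
significant when |mean difference| > 0.1 and padj < 0.05; a chi-squared
goodness-of-fit test measures skew of significant genes toward one
direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust, wilcoxon_rank_sum
from .types import CellTable, GeneModel, IsoformCountMatrix, ValidationError


def laplace_entropy(counts, min_total: int = 10) -> float:
    """Normalized Laplace-smoothed entropy of one gene in one cell.

    Returns NaN (missing) when the gene has a single isoform or the total
    count is below ``min_total``.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValidationError("isoform counts must be nonnegative")
    k = c.size
    if k == 1 or c.sum() < min_total:
        return float("nan")
    p = (c + 1.0) / (c.sum() + k)
    h = -(p * np.log2(p)).sum()
    return float(h / np.log2(k))


def entropy_matrix(icm: IsoformCountMatrix, gm: GeneModel, min_total: int = 10) -> pd.DataFrame:
    """Cells x genes normalized entropy (multi-isoform genes only)."""
    iso_idx: dict = {}
    for j, iso in enumerate(icm.isoform_ids):
        gene = gm.isoform_to_gene.get(iso)
        if gene is None:
            raise ValidationError(f"isoform {iso!r} absent from gene model")
        iso_idx.setdefault(gene, []).append(j)
    out = {}
    for gene, cols in iso_idx.items():
        k = len(cols)
        if k < 2:
            continue
        c = icm.counts[:, cols]
        totals = c.sum(axis=1)
        p = (c + 1.0) / (totals + k)[:, None]
        h = -(p * np.log2(p)).sum(axis=1) / np.log2(k)
        h[totals < min_total] = np.nan
        out[gene] = h
    return pd.DataFrame(out, index=pd.Index(icm.cell_ids, name="cell_id"))


@dataclass
class DiversityComparison:
    """Per-gene differential-entropy table for one group pair."""

    table: pd.DataFrame  # index gene: mean_a, mean_b, diff, p, padj, significant, direction
    group_a: str
    group_b: str
    skipped_genes: list

    @property
    def significant_genes(self) -> list:
        return list(self.table.index[self.table["significant"]])


def differential_entropy(
    em: pd.DataFrame,
    cells: CellTable,
    group_a: Sequence,
    group_b: Sequence,
    diff_min: float = 0.1,
    fdr: float = 0.05,
    min_cells: int = 3,
    name_a: str = "A",
    name_b: str = "B",
) -> DiversityComparison:
    """Two-group entropy comparison over genes with enough defined cells.

    ``group_a``/``group_b`` are cell-id sequences (or population labels
    resolved against ``cells``).  Genes with fewer than ``min_cells``
    defined entropies in either group are skipped and reported.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) == 1 and group_a[0] in set(cells.df["population"]):
        name_a = group_a[0]
        group_a = cells.cells_of(group_a[0])
    if len(group_b) == 1 and group_b[0] in set(cells.df["population"]):
        name_b = group_b[0]
        group_b = cells.cells_of(group_b[0])
    if not group_a or not group_b:
        raise ValidationError("differential entropy requires non-empty groups")
    a = em.loc[[c for c in em.index if c in set(group_a)]]
    b = em.loc[[c for c in em.index if c in set(group_b)]]

    rows, skipped = [], []
    for gene in em.columns:
        va = a[gene].dropna().to_numpy()
        vb = b[gene].dropna().to_numpy()
        if va.size < min_cells or vb.size < min_cells:
            skipped.append(gene)
            continue
        _, p = wilcoxon_rank_sum(va, vb)
        rows.append((gene, va.mean(), vb.mean(), va.mean() - vb.mean(), p))
    table = pd.DataFrame(rows, columns=["gene", "mean_a", "mean_b", "diff", "p"]).set_index("gene")
    table["padj"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    table["significant"] = (table["diff"].abs() > diff_min) & (table["padj"] < fdr)
    table["direction"] = np.where(table["diff"] > 0, "up", "down")
    return DiversityComparison(table, name_a, name_b, skipped)


@dataclass
class SkewTestResult:
    n_up: int
    n_down: int
    chi2: float
    p: float


def skew_test(dc: DiversityComparison) -> SkewTestResult:
    """Chi-squared goodness of fit of significant-gene directions vs 50:50."""
    sig = dc.table[dc.table["significant"]]
    n_up = int((sig["direction"] == "up").sum())
    n_down = int((sig["direction"] == "down").sum())
    n = n_up + n_down
    if n == 0:
        raise ValidationError("no significant genes; skew test is undefined")
    expected = n / 2.0
    chi2 = ((n_up - expected) ** 2 + (n_down - expected) ** 2) / expected
    p = float(stats.chi2.sf(chi2, df=1))
    return SkewTestResult(n_up, n_down, float(chi2), p)
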