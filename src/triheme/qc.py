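"""Cell-quality filters, technical-replicate deduplication, and gene exclusion.

Boundary conventions follow the printed rules strictly: a cell fails with
fewer than 2,000 detected genes, strictly more than 15% mitochondrial or
10% hemoglobin content; a gene is dropped with strictly more than 90%
dropout, and a batch detection-rate difference must strictly exceed 50%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .de import ContrastSpec, run_de
from .types import CellTable, GeneCountMatrix, ValidationError

log = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Outcome of one filtering operation."""

    cell_status: pd.DataFrame  # index cell_id, columns: passed (bool), rules (str)
    retained_cells: list
    removed_replicates: list = field(default_factory=list)
    excluded_genes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "reason"]).set_index("gene")
    )

    def __post_init__(self) -> None:
        failed = set(self.cell_status.index[~self.cell_status["passed"]])
        retained = set(self.retained_cells)
        if failed | retained != set(self.cell_status.index) or failed & retained:
            raise ValidationError("retained and failed cells must partition the input")


def _metrics_from_matrix(gcm: GeneCountMatrix, gene_list: Sequence) -> np.ndarray:
    idx = [i for i, g in enumerate(gcm.gene_ids) if g in set(gene_list)]
    totals = gcm.counts.sum(axis=1)
    part = gcm.counts[:, idx].sum(axis=1) if idx else np.zeros(gcm.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals > 0, 100.0 * part / totals, 0.0)
    return pct


def filter_cells(
    gcm: GeneCountMatrix,
    cells: CellTable,
    min_genes: int = 2000,
    max_mito: float = 15.0,
    max_hb: float = 10.0,
    mito_genes: Optional[Sequence] = None,
    hb_genes: Optional[Sequence] = None,
) -> QCReport:
    """Exclude low-quality cells; boundary values pass.

    Metrics come from the cell table; missing metrics are computed from the
    matrix given mito/hemoglobin gene lists (content as percent of total
    counts, detected genes as count > 0).
    """
    df = cells.df.loc[list(gcm.cell_ids)].copy()

    def _fill(col, values):
        if col not in df.columns or df[col].isna().any():
            if values is None:
                raise ValidationError(f"cell metric {col!r} missing and no gene list supplied")
            computed = pd.Series(values, index=df.index)
            df[col] = df[col].fillna(computed) if col in df.columns else computed

    _fill("n_genes_detected", (gcm.counts > 0).sum(axis=1))
    _fill("pct_mito", _metrics_from_matrix(gcm, mito_genes) if mito_genes is not None else None)
    _fill("pct_hemoglobin", _metrics_from_matrix(gcm, hb_genes) if hb_genes is not None else None)

    fail_genes = df["n_genes_detected"] < min_genes
    fail_mito = df["pct_mito"] > max_mito
    fail_hb = df["pct_hemoglobin"] > max_hb
    rules = pd.Series("", index=df.index, dtype=object)
    for mask, name in ((fail_genes, "min_genes"), (fail_mito, "max_mito"), (fail_hb, "max_hb")):
        rules[mask] = rules[mask].where(rules[mask] == "", rules[mask] + ",") + name
    passed = ~(fail_genes | fail_mito | fail_hb)
    status = pd.DataFrame({"passed": passed, "rules": rules})
    return QCReport(status, retained_cells=list(df.index[passed]))


def dedup_replicates(gcm: GeneCountMatrix, cells: CellTable) -> QCReport:
    """Within each replicate_group keep the cell with most detected genes.

    Ties keep the lexicographically smallest cell_id.  Size-1 groups are
    no-ops (logged).
    """
    df = cells.df.loc[list(gcm.cell_ids)]
    removed: list = []
    if "replicate_group" in df.columns:
        grouped = df[df["replicate_group"].notna()]
        for group, sub in grouped.groupby("replicate_group"):
            if len(sub) == 1:
                log.info("replicate group %r has a single cell; nothing to deduplicate", group)
                continue
            ordered = sub.assign(_id=sub.index).sort_values(
                ["n_genes_detected", "_id"], ascending=[False, True], kind="mergesort"
            )
            removed.extend(list(ordered.index[1:]))
    removed_set = set(removed)
    passed = pd.Series([c not in removed_set for c in df.index], index=df.index)
    status = pd.DataFrame({"passed": passed, "rules": np.where(passed, "", "replicate")})
    return QCReport(status, retained_cells=list(df.index[passed]), removed_replicates=removed)


def filter_dropout_genes(gcm: GeneCountMatrix, groups: Sequence[Sequence], max_dropout: float = 0.90) -> QCReport:
    """Exclude genes with > max_dropout zero-count cells over the contrast cells."""
    cells: list = []
    for g in groups:
        g = list(g)
        if not g:
            raise ValidationError("dropout filter received an empty group")
        cells.extend(g)
    rows = gcm.cell_index(cells)
    dropout = (gcm.counts[rows] == 0).mean(axis=0)
    excluded = [g for g, d in zip(gcm.gene_ids, dropout) if d > max_dropout]
    status = pd.DataFrame({"passed": True, "rules": ""}, index=pd.Index(gcm.cell_ids))
    genes = pd.DataFrame({"reason": "dropout"}, index=pd.Index(excluded, name="gene"))
    return QCReport(status, retained_cells=list(gcm.cell_ids), excluded_genes=genes)


def flag_batch_genes(
    gcm: GeneCountMatrix,
    cells: CellTable,
    bridge_population: str,
    lfc: float = 1.5,
    padj: float = 0.01,
    det_diff: float = 0.50,
) -> QCReport:
    """Flag genes associated with the sequencing batch.

    Within the bridge population (cells of one biological identity sequenced
    in both batches) a gene is flagged if it is differentially expressed
    between batches (|log2FC| > lfc, BH-adjusted p < padj) or if its
    detection rate differs by more than ``det_diff`` between batches.
    """
    df = cells.df.loc[list(gcm.cell_ids)]
    bridge = df[df["population"] == bridge_population]
    batches = sorted(bridge["batch"].dropna().unique())
    if len(batches) < 2:
        raise ValidationError(
            f"bridge population {bridge_population!r} present in {len(batches)} batch(es); need >= 2"
        )
    b1 = list(bridge.index[bridge["batch"] == batches[0]])
    b2 = list(bridge.index[bridge["batch"] == batches[1]])
    contrast = ContrastSpec(b1, b2, name_a=str(batches[0]), name_b=str(batches[1]),
                            lfc=lfc, fdr=padj, pct=0.0)
    res = run_de(gcm, contrast, max_dropout=1.0)
    de_flag = res.index[(res["log2FC"].abs() > lfc) & (res["padj"] < padj)]

    r1 = gcm.cell_index(b1)
    r2 = gcm.cell_index(b2)
    det1 = (gcm.counts[r1] > 0).mean(axis=0)
    det2 = (gcm.counts[r2] > 0).mean(axis=0)
    det_flag = [g for g, d in zip(gcm.gene_ids, np.abs(det1 - det2)) if d > det_diff]

    reasons: dict = {}
    for g in de_flag:
        reasons[g] = "batch-DE"
    for g in det_flag:
        reasons[g] = reasons.get(g, "") + ("," if g in de_flag else "") + "batch-detection"
    genes = pd.DataFrame({"reason": pd.Series(reasons, dtype=object)})
    genes.index.name = "gene"
    status = pd.DataFrame({"passed": True, "rules": ""}, index=pd.Index(gcm.cell_ids))
    return QCReport(status, retained_cells=list(gcm.cell_ids), excluded_genes=genes)
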