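"""Shared domain containers for the three-HE analysis pipeline.

All containers are thin dataclasses around numpy arrays and pandas frames.
Counts are stored dense, cells as rows; at the scale this package targets
(a few thousand Smart-seq2 cells, a few thousand genes) dense arrays are
simpler and faster than sparse ones.  Coordinates are 0-based half-open
internally; GTF input (1-based closed) is converted on read, BED is native.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Input violates a domain invariant (negative count, duplicate id, ...)."""


class FormatError(ValueError):
    """A file does not conform to its declared format."""


POPULATIONS = (
    "ENDO_AGM",
    "ENDO_YS",
    "HE_AGM",
    "HE_YSA",
    "HE_YSP",
    "PROG_P1",
    "PROG_P2",
    "EMP",
    "LMP",
    "OTHER",
)

HE_POPULATIONS = ("HE_AGM", "HE_YSA", "HE_YSP")

#: endothelial trajectory end nearest to each HE population
ENDOTHELIAL_END = {"HE_AGM": "ENDO_AGM", "HE_YSA": "ENDO_YS", "HE_YSP": "ENDO_YS"}

#: most progressed hematopoietic cells, pooled as the hematopoietic end
HEMATOPOIETIC_END = ("EMP", "LMP")


def _check_unique(ids: Sequence[str], what: str) -> list:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{what} must be unique")
    return ids


@dataclass
class IsoformCountMatrix:
    """Cells x isoforms matrix of estimated transcript counts."""

    cell_ids: list
    isoform_ids: list
    counts: np.ndarray  # (n_cells, n_isoforms), nonnegative reals

    def __post_init__(self) -> None:
        self.cell_ids = _check_unique(self.cell_ids, "cell_ids")
        self.isoform_ids = _check_unique(self.isoform_ids, "isoform_ids")
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.cell_ids), len(self.isoform_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.isoform_ids)} isoforms"
            )
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("counts must be finite")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be nonnegative")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_isoforms(self) -> int:
        return len(self.isoform_ids)

    def subset_cells(self, keep: Iterable) -> "IsoformCountMatrix":
        keep = list(keep)
        idx = {c: i for i, c in enumerate(self.cell_ids)}
        rows = [idx[c] for c in keep]
        return IsoformCountMatrix(keep, list(self.isoform_ids), self.counts[rows])


@dataclass
class GeneModel:
    """Isoform-to-gene map plus optional gene coordinates.

    ``coords`` (if present) is a frame indexed by gene_id with columns
    chrom, strand, start, end (0-based half-open).  The transcription start
    site is ``start`` on the + strand and ``end - 1`` on the - strand.
    """

    isoform_to_gene: dict
    coords: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.isoform_to_gene = dict(self.isoform_to_gene)
        if self.coords is not None:
            bad = self.coords[self.coords["start"] >= self.coords["end"]]
            if len(bad):
                raise ValidationError(f"start >= end for genes {list(bad.index[:5])}")
            unknown = set(self.coords["strand"]) - {"+", "-"}
            if unknown:
                raise FormatError(f"unknown strand symbol(s): {sorted(unknown)}")

    @property
    def gene_ids(self) -> list:
        seen: dict = {}
        for g in self.isoform_to_gene.values():
            seen.setdefault(g, None)
        return list(seen)

    @property
    def k(self) -> dict:
        """Number of annotated isoforms per gene."""
        out: dict = {}
        for g in self.isoform_to_gene.values():
            out[g] = out.get(g, 0) + 1
        return out

    def isoforms_of(self, gene_id: str) -> list:
        return [i for i, g in self.isoform_to_gene.items() if g == gene_id]

    @property
    def has_coordinates(self) -> bool:
        return self.coords is not None

    def tss(self) -> pd.Series:
        """TSS position per gene (0-based)."""
        if self.coords is None:
            raise ValidationError("gene model carries no coordinates")
        plus = self.coords["strand"] == "+"
        return self.coords["start"].where(plus, self.coords["end"] - 1)


@dataclass
class CellTable:
    """Per-cell metadata; a frame indexed by unique cell_id.

    Expected columns: population, batch, stage, n_genes_detected, pct_mito,
    pct_hemoglobin, replicate_group (optional, NaN where absent).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            raise ValidationError("cell_id must be unique within the table")
        for col in ("pct_mito", "pct_hemoglobin"):
            if col in self.df.columns:
                vals = self.df[col].dropna()
                if ((vals < 0) | (vals > 100)).any():
                    raise ValidationError(f"{col} must lie in [0, 100]")

    @property
    def cell_ids(self) -> list:
        return list(self.df.index)

    def cells_of(self, population: str) -> list:
        return list(self.df.index[self.df["population"] == population])

    def subset(self, keep: Iterable) -> "CellTable":
        return CellTable(self.df.loc[list(keep)].copy())


@dataclass
class GeneCountMatrix:
    """Cells x genes counts, with an optional log-normalized layer."""

    cell_ids: list
    gene_ids: list
    counts: np.ndarray
    normalized: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.cell_ids = _check_unique(self.cell_ids, "cell_ids")
        self.gene_ids = _check_unique(self.gene_ids, "gene_ids")
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError("counts shape does not match ids")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be nonnegative")
        if self.normalized is not None:
            self.normalized = np.asarray(self.normalized, dtype=float)
            if self.normalized.shape != self.counts.shape:
                raise FormatError("normalized layer shape mismatch")
            if np.any(self.normalized < 0):
                raise ValidationError("normalized values must be nonnegative")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def cell_index(self, cells: Iterable) -> np.ndarray:
        idx = {c: i for i, c in enumerate(self.cell_ids)}
        return np.array([idx[c] for c in cells], dtype=int)

    def subset_cells(self, keep: Iterable) -> "GeneCountMatrix":
        keep = list(keep)
        rows = self.cell_index(keep)
        norm = self.normalized[rows] if self.normalized is not None else None
        return GeneCountMatrix(keep, list(self.gene_ids), self.counts[rows], norm)

    def subset_genes(self, keep: Iterable) -> "GeneCountMatrix":
        keep = list(keep)
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        cols = np.array([idx[g] for g in keep], dtype=int)
        norm = self.normalized[:, cols] if self.normalized is not None else None
        return GeneCountMatrix(list(self.cell_ids), keep, self.counts[:, cols], norm)


@dataclass
class Signature:
    """Named gene set used for per-cell rank-based scoring."""

    name: str
    genes: list

    def __post_init__(self) -> None:
        self.genes = list(dict.fromkeys(self.genes))  # de-duplicate, keep order
        if len(self.genes) < 1:
            raise ValidationError(f"signature {self.name!r} is empty")
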