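"""Readers and writers for the pipeline's plain-text formats.

MatrixMarket count matrices with one-column TSV sidecars, GTF or two-column
TSV gene models, cell annotation TSVs, signature TSV/JSON, and BED peaks.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import (
    CellTable,
    FormatError,
    GeneCountMatrix,
    GeneModel,
    IsoformCountMatrix,
    Signature,
    ValidationError,
)


def _read_ids(path) -> list:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_isoform_matrix(path_mtx, path_isoforms, path_cells, *, cells_as_rows: bool = True) -> IsoformCountMatrix:
    """Read a MatrixMarket coordinate matrix plus id sidecars.

    ``cells_as_rows`` declares the orientation of the MTX file; internally
    cells are always rows.
    """
    mat = scipy.io.mmread(str(path_mtx))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    if not cells_as_rows:
        mat = mat.T
    cells = _read_ids(path_cells)
    isoforms = _read_ids(path_isoforms)
    if mat.shape != (len(cells), len(isoforms)):
        raise FormatError(
            f"MTX shape {mat.shape} does not match sidecars "
            f"({len(cells)} cells, {len(isoforms)} isoforms)"
        )
    return IsoformCountMatrix(cells, isoforms, mat)


def write_isoform_matrix(icm: IsoformCountMatrix, path_mtx, path_isoforms, path_cells) -> None:
    sp = scipy.sparse.coo_matrix(icm.counts)
    # integer field when counts are whole numbers, for bit-exact round-trips
    if np.all(icm.counts == np.round(icm.counts)):
        sp = sp.astype(np.int64)
    scipy.io.mmwrite(str(path_mtx), sp)
    Path(path_cells).write_text("".join(f"{c}\n" for c in icm.cell_ids))
    Path(path_isoforms).write_text("".join(f"{i}\n" for i in icm.isoform_ids))


def _parse_gtf_attributes(attr: str) -> dict:
    out = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gene_model(path) -> GeneModel:
    """Read a gene model from GTF (transcript features) or 2-column TSV.

    The TSV dialect is isoform_id<TAB>gene_id with no coordinates; a model
    built from it refuses coordinate-dependent operations downstream.
    """
    path = Path(path)
    text = path.read_text()
    first_data = next((l for l in text.splitlines() if l.strip() and not l.startswith("#")), "")
    if first_data.count("\t") == 1:
        return _read_gene_model_tsv(text)
    return _read_gene_model_gtf(text)


def _read_gene_model_tsv(text: str) -> GeneModel:
    iso2gene: dict = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"expected 2 TSV columns, got {len(fields)}: {line!r}")
        iso, gene = fields
        if iso in iso2gene and iso2gene[iso] != gene:
            raise ValidationError(f"isoform {iso!r} mapped to both {iso2gene[iso]!r} and {gene!r}")
        iso2gene[iso] = gene
    return GeneModel(iso2gene, coords=None)


def _read_gene_model_gtf(text: str) -> GeneModel:
    iso2gene: dict = {}
    rows: dict = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise FormatError(f"GTF line has {len(fields)} fields: {line[:80]!r}")
        chrom, _, feature, start, end, _, strand, _, attr = fields[:9]
        if feature != "transcript":
            continue
        if strand not in ("+", "-"):
            raise FormatError(f"unknown strand symbol {strand!r}")
        attrs = _parse_gtf_attributes(attr)
        try:
            gene, iso = attrs["gene_id"], attrs["transcript_id"]
        except KeyError as exc:
            raise FormatError(f"GTF transcript lacks {exc} attribute") from exc
        if iso in iso2gene and iso2gene[iso] != gene:
            raise ValidationError(f"transcript {iso!r} listed under {iso2gene[iso]!r} and {gene!r}")
        iso2gene[iso] = gene
        s0, e0 = int(start) - 1, int(end)  # GTF is 1-based closed
        if gene in rows:
            r = rows[gene]
            rows[gene] = (r[0], min(r[1], s0), max(r[2], e0), r[3])
        else:
            rows[gene] = (chrom, s0, e0, strand)
    coords = pd.DataFrame.from_dict(rows, orient="index", columns=["chrom", "start", "end", "strand"])
    coords.index.name = "gene_id"
    return GeneModel(iso2gene, coords=coords)


def write_gene_model_gtf(gm: GeneModel, path) -> None:
    if gm.coords is None:
        raise ValidationError("gene model carries no coordinates; write the TSV form instead")
    lines = []
    for iso, gene in gm.isoform_to_gene.items():
        row = gm.coords.loc[gene]
        lines.append(
            f"{row['chrom']}\ttriheme\ttranscript\t{int(row['start']) + 1}\t{int(row['end'])}\t.\t"
            f"{row['strand']}\t.\tgene_id \"{gene}\"; transcript_id \"{iso}\";"
        )
    Path(path).write_text("".join(l + "\n" for l in lines))


def read_cell_table(path) -> CellTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CellTable(df)


def write_cell_table(cells: CellTable, path) -> None:
    cells.df.to_csv(path, sep="\t", index_label="cell_id")


def read_signatures(path) -> list:
    """Signatures from a 2-column TSV (signature_name, gene) or a JSON map."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return [Signature(name, genes) for name, genes in data.items()]
    df = pd.read_csv(path, sep="\t", header=None, names=["signature", "gene"], comment="#")
    return [Signature(name, list(sub["gene"])) for name, sub in df.groupby("signature", sort=False)]


def write_signatures(signatures, path) -> None:
    Path(path).write_text(json.dumps({s.name: s.genes for s in signatures}, indent=2))


def read_bed(path) -> pd.DataFrame:
    """BED3+ intervals (0-based half-open)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"BED line has fewer than 3 columns: {line!r}")
        rows.append((fields[0], int(fields[1]), int(fields[2])))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if ((df["end"] - df["start"]) <= 0).any():
        raise ValidationError("BED intervals must satisfy start < end")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def aggregate_to_genes(icm: IsoformCountMatrix, gm: GeneModel) -> GeneCountMatrix:
    """Sum isoform counts to gene counts per cell; conserves cell totals."""
    unmapped = [i for i in icm.isoform_ids if i not in gm.isoform_to_gene]
    if unmapped:
        raise ValidationError(f"isoforms not in gene model: {unmapped[:10]}"
                              + ("..." if len(unmapped) > 10 else ""))
    genes = list(dict.fromkeys(gm.isoform_to_gene[i] for i in icm.isoform_ids))
    gidx = {g: j for j, g in enumerate(genes)}
    cols = np.array([gidx[gm.isoform_to_gene[i]] for i in icm.isoform_ids])
    counts = np.zeros((icm.n_cells, len(genes)))
    np.add.at(counts.T, cols, icm.counts.T)
    return GeneCountMatrix(list(icm.cell_ids), genes, counts)


def log_normalize(gcm: GeneCountMatrix, scale: float = 1e4) -> GeneCountMatrix:
    """Counts-per-10k log2 normalization: log2(1 + scale * c / cell_total)."""
    totals = gcm.counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        bad = [gcm.cell_ids[i] for i in zero[:5]]
        raise ValidationError(
            f"cells with zero total counts (e.g. {bad}); apply cell QC before normalizing"
        )
    norm = np.log2(1.0 + scale * gcm.counts / totals[:, None])
    return GeneCountMatrix(list(gcm.cell_ids), list(gcm.gene_ids), gcm.counts, norm)
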