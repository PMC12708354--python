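"""Peak-based transcription-factor target annotation.

ChIP-seq peaks hit a gene when the peak interval lies within ``chip_window``
(default 3 kb) of the transcription start site; DamID peaks when within
``damid_window`` (default 5 kb) of the gene body.  Distances are
edge-to-edge on the genomic continuum (overlap = 0), boundaries inclusive.
A gene is called a GFI target when it is bound in at least one GFI1 dataset
AND at least one GFI1B dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import GeneModel, ValidationError

FACTORS = ("GFI1", "GFI1B")
ASSAYS = ("CHIP", "DAMID")


@dataclass
class PeakSet:
    """BED intervals from one binding dataset."""

    intervals: pd.DataFrame  # chrom, start, end (0-based half-open)
    label: str
    factor: str
    assay: str

    def __post_init__(self) -> None:
        self.factor = self.factor.upper()
        self.assay = self.assay.upper()
        if self.factor not in FACTORS:
            raise ValidationError(f"factor must be one of {FACTORS}, got {self.factor!r}")
        if self.assay not in ASSAYS:
            raise ValidationError(f"assay must be one of {ASSAYS}, got {self.assay!r}")
        if ((self.intervals["end"] - self.intervals["start"]) <= 0).any():
            raise ValidationError("peak intervals must satisfy start < end")


def _min_distance_to_point(starts: np.ndarray, ends: np.ndarray, point: int) -> float:
    """Minimum edge distance from intervals to a point (overlap = 0)."""
    return float(np.maximum(np.maximum(starts - point, point - ends), 0).min())


def _min_distance_to_interval(starts, ends, gs: int, ge: int) -> float:
    return float(np.maximum(np.maximum(starts - ge, gs - ends), 0).min())


def annotate_peaks(
    peakset: PeakSet,
    gm: GeneModel,
    chip_window: int = 3000,
    damid_window: int = 5000,
) -> pd.DataFrame:
    """Per-gene hit calls for one dataset.

    Returns a frame indexed by gene with columns ``distance`` (nearest peak
    edge distance, NaN when the chromosome has no peaks) and ``hit``.
    Unassignable peaks (chromosome absent from the gene model) are counted
    in ``annotate_peaks.unassigned`` on the returned frame's attrs.
    """
    if not gm.has_coordinates:
        raise ValidationError("gene model carries no coordinates; peak annotation needs a GTF model")
    window = chip_window if peakset.assay == "CHIP" else damid_window
    tss = gm.tss()
    by_chrom = {c: sub for c, sub in peakset.intervals.groupby("chrom")}
    model_chroms = set(gm.coords["chrom"])
    unassigned = int(sum(len(sub) for c, sub in by_chrom.items() if c not in model_chroms))
    rows = []
    for gene, row in gm.coords.iterrows():
        sub = by_chrom.get(row["chrom"])
        if sub is None or not len(sub):
            rows.append((gene, np.nan, False))
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if peakset.assay == "CHIP":
            d = _min_distance_to_point(starts, ends, int(tss.loc[gene]))
        else:
            d = _min_distance_to_interval(starts, ends, int(row["start"]), int(row["end"]))
        rows.append((gene, d, d <= window))
    out = pd.DataFrame(rows, columns=["gene", "distance", "hit"]).set_index("gene")
    out.attrs["unassigned_peaks"] = unassigned
    out.attrs["dataset"] = peakset.label
    return out


def call_targets(hits: Mapping[str, pd.DataFrame], factors: Mapping[str, str]) -> pd.DataFrame:
    """Combine per-dataset hit tables into target calls.

    ``hits`` maps dataset label to an annotate_peaks frame; ``factors`` maps
    dataset label to its factor.  A gene is a target iff bound in >= 1 GFI1
    and >= 1 GFI1B dataset.
    """
    present = {factors[lab].upper() for lab in hits}
    if not {"GFI1", "GFI1B"} <= present:
        raise ValidationError(f"need at least one dataset per factor GFI1 and GFI1B; got {sorted(present)}")
    genes = sorted(set.union(*(set(df.index) for df in hits.values())))
    rows = []
    for gene in genes:
        bound = [lab for lab, df in hits.items() if gene in df.index and bool(df.loc[gene, "hit"])]
        bound_factors = {factors[lab].upper() for lab in bound}
        rows.append((gene, ",".join(sorted(bound)), {"GFI1", "GFI1B"} <= bound_factors))
    return pd.DataFrame(rows, columns=["gene", "bound_datasets", "is_target"]).set_index("gene")


def intersect_with_profile(targets: pd.DataFrame, profile_genes: Sequence) -> pd.DataFrame:
    """Flag profile genes that are targets; summary fraction in attrs."""
    profile_genes = list(dict.fromkeys(profile_genes))
    if not profile_genes:
        raise ValidationError("profile gene set is empty")
    target_set = set(targets.index[targets["is_target"]])
    out = pd.DataFrame(
        {"is_target": [g in target_set for g in profile_genes]},
        index=pd.Index(profile_genes, name="gene"),
    )
    out.attrs["fraction_targets"] = float(out["is_target"].mean())
    return out
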