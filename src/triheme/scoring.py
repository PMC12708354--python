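"""Per-cell rank-based gene-signature scoring.

The score is a capped Mann-Whitney U statistic: genes are ranked per cell
by decreasing expression (average ranks for ties; undetected genes share
tied ranks at the bottom), ranks beyond ``r_max`` are truncated to
``r_max + 1``, and for a signature of n genes

    U = sum of signature ranks - n(n+1)/2,     score = 1 - U / (n * r_max)

clipped to [0, 1].  A score of 1 means the signature occupies the top n
ranks; 0 means every signature gene ranks beyond r_max.  Being rank-based,
the score is invariant to any monotone transform of the expression vector.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust, wilcoxon_rank_sum
from .types import CellTable, GeneCountMatrix, Signature, ValidationError


def _signature_columns(universe: Sequence, sig: Signature) -> list:
    present = [g for g in sig.genes if g in set(universe)]
    missing = [g for g in sig.genes if g not in set(universe)]
    if missing:
        warnings.warn(
            f"signature {sig.name!r}: {len(missing)} gene(s) absent from the universe "
            f"and excluded (e.g. {missing[:3]})"
        )
    if not present:
        raise ValidationError(f"no gene of signature {sig.name!r} is in the expression universe")
    return present


def _capped_ranks(expr: np.ndarray, r_max: int) -> np.ndarray:
    ranks = stats.rankdata(-expr, axis=-1, method="average")
    return np.minimum(ranks, r_max + 1)


def score_cell(expr, universe: Sequence, sig: Signature, r_max: int = 1500) -> float:
    """Signature score of a single expression vector over ``universe``."""
    expr = np.asarray(expr, dtype=float)
    genes = _signature_columns(universe, sig)
    n = len(genes)
    if n > r_max:
        raise ValidationError(f"signature size {n} exceeds r_max={r_max}")
    idx = {g: i for i, g in enumerate(universe)}
    cols = [idx[g] for g in genes]
    ranks = _capped_ranks(expr, r_max)
    u = ranks[cols].sum() - n * (n + 1) / 2.0
    return float(np.clip(1.0 - u / (n * r_max), 0.0, 1.0))


def score_matrix(gcm: GeneCountMatrix, signatures: Sequence[Signature], r_max: int = 1500) -> pd.DataFrame:
    """Cells x signatures score frame, computed on the normalized layer."""
    if not signatures:
        raise ValidationError("at least one signature is required")
    expr = gcm.normalized if gcm.normalized is not None else gcm.counts
    ranks = _capped_ranks(expr, r_max)
    idx = {g: i for i, g in enumerate(gcm.gene_ids)}
    out = {}
    for sig in signatures:
        genes = _signature_columns(gcm.gene_ids, sig)
        n = len(genes)
        if n > r_max:
            raise ValidationError(f"signature size {n} exceeds r_max={r_max}")
        cols = [idx[g] for g in genes]
        u = ranks[:, cols].sum(axis=1) - n * (n + 1) / 2.0
        out[sig.name] = np.clip(1.0 - u / (n * r_max), 0.0, 1.0)
    return pd.DataFrame(out, index=pd.Index(gcm.cell_ids, name="cell_id"))


def compare_scores(scores: pd.DataFrame, cells: CellTable, pairs: Sequence) -> pd.DataFrame:
    """Pairwise two-sided rank-sum comparisons of signature scores.

    ``pairs`` is a sequence of (population_a, population_b); BH adjustment
    is applied across every (pair, signature) comparison in the call.
    """
    pops = cells.df["population"]
    rows = []
    for pop_a, pop_b in pairs:
        for pop in (pop_a, pop_b):
            if pop not in set(pops):
                raise ValidationError(f"unknown population {pop!r}")
        a_cells = [c for c in scores.index if pops.get(c) == pop_a]
        b_cells = [c for c in scores.index if pops.get(c) == pop_b]
        if not a_cells or not b_cells:
            raise ValidationError(f"pair ({pop_a}, {pop_b}) has an empty side")
        for sig in scores.columns:
            _, p = wilcoxon_rank_sum(scores.loc[a_cells, sig], scores.loc[b_cells, sig])
            rows.append((pop_a, pop_b, sig, p))
    out = pd.DataFrame(rows, columns=["population_a", "population_b", "signature", "p"])
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out
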