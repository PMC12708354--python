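"""Two-group differential expression on log-normalized values.

The statistic is a Wilcoxon rank-sum (Mann-Whitney U) test with a
mean-difference log2 fold change, Benjamini-Hochberg FDR control, and the
expressing-cell fractions used by every downstream threshold rule.  Genes
with more than ``max_dropout`` zero-count cells across the contrast are
excluded before testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import GeneCountMatrix, ValidationError


def _exact_ranksum(x: np.ndarray, y: np.ndarray) -> tuple:
    """Exhaustive permutation enumeration of the rank-sum U statistic.

    Two-sided p: fraction of the C(n, n_x) group labelings whose U deviates
    from its null mean n_x*n_y/2 at least as much as observed.  Exact under
    ties; coincides with the classical exact distribution without ties.
    """
    from itertools import combinations

    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    obs_u = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    dev = abs(obs_u - nx * ny / 2.0)
    hits = total = 0
    for combo in combinations(range(nx + ny), nx):
        u = ranks[list(combo)].sum() - nx * (nx + 1) / 2.0
        hits += abs(u - nx * ny / 2.0) >= dev - 1e-12
        total += 1
    return float(obs_u), hits / total


def wilcoxon_rank_sum(x, y, force_exact: bool = False) -> tuple:
    """Two-sided rank-sum test; (U statistic of x, p).

    Exact enumeration of all group labelings when the pooled sample is
    small (<=12), otherwise a tie- and continuity-corrected normal
    approximation.  ``force_exact`` extends enumeration to larger samples
    (as long as the arrangement count stays enumerable).
    """
    from math import comb

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank-sum test requires non-empty samples")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2.0), 1.0
    n = pooled.size
    if n <= 12 or (force_exact and comb(n, x.size) <= 200_000):
        return _exact_ranksum(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                             use_continuity=True)
    p = float(res.pvalue)
    if not np.isfinite(p):
        p = 1.0
    return float(res.statistic), float(min(max(p, np.finfo(float).tiny), 1.0))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, mapped back to input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = q
    return out


@dataclass
class ContrastSpec:
    """Two disjoint cell groups plus the thresholds applied to the result."""

    group_a: Sequence
    group_b: Sequence
    name_a: str = "A"
    name_b: str = "B"
    lfc: float = 1.0
    fdr: float = 0.05
    pct: float = 0.0

    def __post_init__(self) -> None:
        self.group_a = list(self.group_a)
        self.group_b = list(self.group_b)
        if not self.group_a or not self.group_b:
            raise ValidationError("contrast groups must be non-empty")
        if set(self.group_a) & set(self.group_b):
            raise ValidationError("contrast groups must be disjoint")


def _ranksum_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise two-sided asymptotic rank-sum p-values (tie-corrected)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True, axis=0)
    p = np.asarray(res.pvalue, dtype=float)
    p[~np.isfinite(p)] = 1.0  # constant columns: no evidence
    return np.clip(p, np.finfo(float).tiny, 1.0)


def run_de(gcm: GeneCountMatrix, contrast: ContrastSpec, max_dropout: float = 0.90) -> pd.DataFrame:
    """Per-gene DE between the contrast's groups.

    Returns a frame indexed by gene with columns log2FC (mean A - mean B on
    the normalized scale), p, padj, pct_expr_a/b, n_a/n_b, and threshold
    flags up_in_a / up_in_b / significant per the ContrastSpec (the pct rule
    applies to the upregulated group).
    """
    if gcm.normalized is None:
        raise ValidationError("run_de requires a log-normalized matrix")
    ia = gcm.cell_index(contrast.group_a)
    ib = gcm.cell_index(contrast.group_b)
    union = np.concatenate([ia, ib])
    raw = gcm.counts[union]
    dropout = (raw == 0).mean(axis=0)
    keep = dropout <= max_dropout  # excluded iff strictly more than max_dropout zeros
    genes = [g for g, k in zip(gcm.gene_ids, keep) if k]
    cols = np.flatnonzero(keep)

    a = gcm.normalized[np.ix_(ia, cols)]
    b = gcm.normalized[np.ix_(ib, cols)]
    ca = gcm.counts[np.ix_(ia, cols)]
    cb = gcm.counts[np.ix_(ib, cols)]

    small = min(len(ia), len(ib)) < 3
    if small:
        warnings.warn("a contrast group has fewer than 3 cells; exact rank-sum enforced")
    if small or (len(ia) + len(ib)) <= 12:
        p = np.array([wilcoxon_rank_sum(a[:, j], b[:, j], force_exact=small)[1]
                      for j in range(a.shape[1])])
    else:
        p = _ranksum_matrix(a, b)

    log2fc = a.mean(axis=0) - b.mean(axis=0)
    padj = bh_adjust(p)
    pct_a = (ca > 0).mean(axis=0)
    pct_b = (cb > 0).mean(axis=0)
    up_a = (log2fc > contrast.lfc) & (padj < contrast.fdr) & (pct_a > contrast.pct)
    up_b = (-log2fc > contrast.lfc) & (padj < contrast.fdr) & (pct_b > contrast.pct)
    return pd.DataFrame(
        {
            "log2FC": log2fc,
            "p": p,
            "padj": padj,
            "pct_expr_a": pct_a,
            "pct_expr_b": pct_b,
            "n_a": len(ia),
            "n_b": len(ib),
            "up_in_a": up_a,
            "up_in_b": up_b,
            "significant": up_a | up_b,
        },
        index=pd.Index(genes, name="gene"),
    )


def downsample_equal(clusters: Mapping, seed: int) -> dict:
    """Subsample each cluster, without replacement, to the smallest cluster size.

    ``clusters`` maps cluster name to a sequence of cell ids.  Clusters
    already at the minimum size are returned unchanged; sampling is
    deterministic in ``seed``.
    """
    clusters = {k: list(v) for k, v in clusters.items()}
    for name, cells in clusters.items():
        if not cells:
            raise ValidationError(f"cluster {name!r} is empty")
    n_min = min(len(v) for v in clusters.values())
    rng = np.random.default_rng(seed)
    out = {}
    for name in clusters:
        cells = clusters[name]
        if len(cells) == n_min:
            out[name] = list(cells)
        else:
            idx = np.sort(rng.choice(len(cells), size=n_min, replace=False))
            out[name] = [cells[i] for i in idx]
    return out
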