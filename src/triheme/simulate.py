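"""Synthetic Smart-seq2-like isoform-level datasets with planted truth.

The generator emulates the statistical structure the downstream analyses
assume: per-gene negative-binomial sequencing depth with dropout, and a
per-gene isoform-usage vector pi drawn from a Dirichlet and shared by all
cells of a population (so usage differences reflect population-level
balance, not cell-to-cell noise).  Planted gene classes provide ground
truth for every stage:

* ``he_restricted`` / ``endothelial_biased`` / ``hematopoietic_biased`` -
  fold changes shaping the shared-HE-profile arms;
* ``emp_fate`` / ``lmp_fate`` - concordant fold changes in EMP-vs-LMP and
  progenitor p2-vs-p1;
* ``interhe_up_<HE>`` - markers upregulated in a single HE population;
* ``entropy_shift`` - balanced usage (high Dirichlet concentration) in
  HE_AGM versus a dominant isoform (low concentration) elsewhere;
* ``switch`` - a delta-sized transfer of usage mass between the two top
  isoforms between HE_AGM and the other populations (target pooled dIF);
* ``batch`` - a multiplicative depth effect tied to the sequencing batch,
  not to any population.

Non-planted genes share a single usage vector across all populations, so
they are true nulls for the entropy and dIF tests.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    CellTable,
    GeneModel,
    HE_POPULATIONS,
    IsoformCountMatrix,
    ValidationError,
)


def _default_populations() -> Dict[str, int]:
    return {
        "ENDO_AGM": 100,
        "ENDO_YS": 100,
        "HE_AGM": 100,
        "HE_YSA": 100,
        "HE_YSP": 100,
        "PROG_P1": 100,
        "PROG_P2": 100,
        "EMP": 100,
        "LMP": 100,
    }


def _default_k_probs() -> Dict[int, float]:
    # isoform multiplicity distribution, truncated at 8
    return {1: 0.25, 2: 0.25, 3: 0.20, 4: 0.12, 5: 0.08, 6: 0.05, 7: 0.03, 8: 0.02}


@dataclass
class SimConfig:
    """Generator parameters; defaults are the package's study conditions."""

    n_cells: Dict[str, int] = field(default_factory=_default_populations)
    n_genes: int = 2000
    k_probs: Dict[int, float] = field(default_factory=_default_k_probs)
    alpha_base: float = 1.0  # usage concentration of null genes
    alpha_high: float = 5.0  # balanced usage (high entropy)
    alpha_low: float = 0.2  # dominant isoform (low entropy)
    depth_mean: float = 100.0  # NB mean per gene before per-gene jitter
    depth_lognorm_sigma: float = 0.5
    dispersion: float = 2.0  # NB size; variance = mu + mu^2/dispersion
    dropout: float = 0.15
    fold_change: float = 6.0  # planted DE fold factor
    batch_fold: float = 8.0
    delta_dif: float = 0.3  # planted switch usage shift
    n_he_restricted: int = 10
    n_endothelial_biased: int = 120
    n_hematopoietic_biased: int = 80
    n_emp_fate: int = 10
    n_lmp_fate: int = 10
    n_interhe_up: int = 30  # per HE population
    n_entropy_shift: int = 100
    n_switch: int = 50
    n_batch_genes: int = 20
    n_factors: int = 300  # curated transcription/chromatin factor list size
    seed: int = 0

    def validate(self) -> None:
        if min(self.alpha_base, self.alpha_high, self.alpha_low) <= 0:
            raise ValidationError("Dirichlet concentrations must be positive")
        if self.depth_mean <= 0 or self.dispersion <= 0:
            raise ValidationError("depth_mean and dispersion must be positive")
        if not 0 <= self.dropout < 1:
            raise ValidationError("dropout must lie in [0, 1)")
        if not 0 < self.delta_dif <= 1:
            raise ValidationError("delta_dif must lie in (0, 1]")
        if abs(sum(self.k_probs.values()) - 1.0) > 1e-9:
            raise ValidationError("k_probs must sum to 1")
        n_planted = (
            self.n_he_restricted + self.n_endothelial_biased + self.n_hematopoietic_biased
            + self.n_emp_fate + self.n_lmp_fate + 3 * self.n_interhe_up
            + self.n_entropy_shift + self.n_switch + self.n_batch_genes
        )
        if n_planted > self.n_genes:
            raise ValidationError(f"{n_planted} planted genes exceed n_genes={self.n_genes}")


#: populations whose depth multiplier each planted expression class raises
_CLASS_POPULATIONS = {
    "he_restricted": ("HE_AGM", "HE_YSA", "HE_YSP"),
    "endothelial_biased": ("ENDO_AGM", "ENDO_YS", "HE_AGM", "HE_YSA", "HE_YSP"),
    "hematopoietic_biased": ("HE_AGM", "HE_YSA", "HE_YSP", "PROG_P1", "PROG_P2", "EMP", "LMP"),
    "emp_fate": ("EMP", "PROG_P2"),
    "lmp_fate": ("LMP", "PROG_P1"),
    "interhe_up_HE_AGM": ("HE_AGM",),
    "interhe_up_HE_YSA": ("HE_YSA",),
    "interhe_up_HE_YSP": ("HE_YSP",),
}

#: batch layout: AGM material in batch1, YS material in batch2, with the
#: ENDO_AGM bridge population split across both batches
_BATCH1_POPULATIONS = ("HE_AGM",)
_BRIDGE_POPULATION = "ENDO_AGM"


@dataclass
class SimOutput:
    icm: IsoformCountMatrix
    gene_model: GeneModel
    cells: CellTable
    gene_truth: pd.DataFrame  # index gene: class, fold, delta, direction
    cell_truth: pd.DataFrame  # planted QC violations (empty until planted)
    factors: list
    config: SimConfig

    def genes_of_class(self, cls: str) -> list:
        return list(self.gene_truth.index[self.gene_truth["class"] == cls])


def _draw_usage(rng: np.random.Generator, k: int, alpha: float) -> np.ndarray:
    return rng.dirichlet(np.full(k, alpha))


def _switch_usage(rng: np.random.Generator, k: int, alpha_low: float, delta: float) -> tuple:
    """Usage pair (pi_a, pi_b) whose top-two isoforms differ by +-delta."""
    pi = np.sort(_draw_usage(rng, k, alpha_low))[::-1]
    # guarantee enough transferable mass on the dominant isoform
    need = min(delta + 0.05, 0.95)
    if pi[0] < need:
        e0 = np.zeros(k)
        e0[0] = 1.0
        w = (need - pi[0]) / (1.0 - pi[0])
        pi = (1 - w) * pi + w * e0
    pi_b = pi.copy()
    pi_b[0] -= delta
    pi_b[1] += delta
    return pi, pi_b


def simulate(config: SimConfig) -> SimOutput:
    """Generate a dataset under ``config``; reproducible given its seed."""
    config.validate()
    pops = list(config.n_cells)
    for cls, needed in _CLASS_POPULATIONS.items():
        n_attr = "n_interhe_up" if cls.startswith("interhe_up") else f"n_{cls}"
        if getattr(config, n_attr) > 0:
            missing = [p for p in needed if p not in config.n_cells]
            if missing:
                raise ValidationError(f"planted class {cls!r} references absent population(s) {missing}")
    rng = np.random.default_rng(config.seed)

    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    ks = rng.choice(list(config.k_probs), size=config.n_genes, p=list(config.k_probs.values()))

    # assign planted classes to disjoint gene blocks
    classes = np.array(["null"] * config.n_genes, dtype=object)
    cursor = 0
    blocks = [
        ("he_restricted", config.n_he_restricted),
        ("endothelial_biased", config.n_endothelial_biased),
        ("hematopoietic_biased", config.n_hematopoietic_biased),
        ("emp_fate", config.n_emp_fate),
        ("lmp_fate", config.n_lmp_fate),
        ("interhe_up_HE_AGM", config.n_interhe_up),
        ("interhe_up_HE_YSA", config.n_interhe_up),
        ("interhe_up_HE_YSP", config.n_interhe_up),
        ("entropy_shift", config.n_entropy_shift),
        ("switch", config.n_switch),
        ("batch", config.n_batch_genes),
    ]
    for cls, n in blocks:
        classes[cursor : cursor + n] = cls
        cursor += n
    # isoform-usage classes need at least two isoforms
    multi_ks = [k for k in config.k_probs if k >= 2]
    multi_p = np.array([config.k_probs[k] for k in multi_ks])
    multi_p = multi_p / multi_p.sum()
    iso_planted = np.isin(classes, ("entropy_shift", "switch"))
    ks[iso_planted] = rng.choice(multi_ks, size=int(iso_planted.sum()), p=multi_p)

    # gene model: isoforms + synthetic coordinates (one chromosome per 200 genes)
    iso2gene: dict = {}
    for g, k in zip(genes, ks):
        for t in range(int(k)):
            iso2gene[f"{g}.t{t + 1}"] = g
    coords = pd.DataFrame(
        {
            "chrom": [f"chr{1 + i // 200}" for i in range(config.n_genes)],
            "start": [10_000 + 50_000 * (i % 200) for i in range(config.n_genes)],
            "strand": np.where(rng.random(config.n_genes) < 0.5, "+", "-"),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    coords["end"] = coords["start"] + rng.integers(2_000, 20_000, size=config.n_genes)
    gm = GeneModel(iso2gene, coords=coords[["chrom", "start", "end", "strand"]])

    # per-gene base depth and per-population multipliers
    base_mu = config.depth_mean * rng.lognormal(0.0, config.depth_lognorm_sigma, size=config.n_genes)
    mult = {p: np.ones(config.n_genes) for p in pops}
    for i, cls in enumerate(classes):
        if cls in _CLASS_POPULATIONS:
            for p in _CLASS_POPULATIONS[cls]:
                mult[p][i] = config.fold_change

    # usage vectors: one shared draw per null gene; population-specific for planted
    usage: dict = {p: [None] * config.n_genes for p in pops}
    for i, (cls, k) in enumerate(zip(classes, ks)):
        k = int(k)
        if cls == "entropy_shift":
            hi = _draw_usage(rng, k, config.alpha_high)
            lo = _draw_usage(rng, k, config.alpha_low)
            for p in pops:
                usage[p][i] = hi if p == "HE_AGM" else lo
        elif cls == "switch":
            pi_a, pi_b = _switch_usage(rng, k, config.alpha_low, config.delta_dif)
            for p in pops:
                usage[p][i] = pi_a if p == "HE_AGM" else pi_b
        else:
            pi = _draw_usage(rng, k, config.alpha_base)
            for p in pops:
                usage[p][i] = pi

    # cells, batches and metadata
    cell_rows = []
    for p in pops:
        n = config.n_cells[p]
        if n < 1:
            raise ValidationError(f"population {p!r} has no cells")
        for j in range(n):
            if p in _BATCH1_POPULATIONS:
                batch = "batch1"
            elif p == _BRIDGE_POPULATION:
                batch = "batch1" if j < n // 2 else "batch2"
            else:
                batch = "batch2"
            cell_rows.append((f"{p}_c{j:04d}", p, batch))
    cell_df = pd.DataFrame(cell_rows, columns=["cell_id", "population", "batch"]).set_index("cell_id")
    n_total = len(cell_df)
    cell_df["stage"] = np.where(cell_df["population"].isin(("HE_YSP", "PROG_P2", "EMP")), "E9.5", "E10.5")
    cell_df["n_genes_detected"] = np.clip(
        np.round(rng.normal(6553, 800, size=n_total)), 2500, None
    ).astype(int)
    cell_df["pct_mito"] = rng.uniform(1.0, 10.0, size=n_total)
    cell_df["pct_hemoglobin"] = rng.uniform(0.0, 5.0, size=n_total)
    cell_df["replicate_group"] = pd.Series([None] * n_total, index=cell_df.index, dtype=object)

    # counts: NB depth with dropout, then a multinomial split across isoforms
    iso_ids = list(iso2gene)
    iso_offsets = np.concatenate([[0], np.cumsum(ks.astype(int))])
    counts = np.zeros((n_total, len(iso_ids)))
    row0 = 0
    disp = config.dispersion
    for p in pops:
        n = config.n_cells[p]
        mu = base_mu * mult[p]
        is_batch2 = (cell_df["batch"].iloc[row0 : row0 + n] == "batch2").to_numpy()
        batch_mult = np.ones((n, config.n_genes))
        batch_mult[is_batch2[:, None] & (classes == "batch")[None, :]] = config.batch_fold
        nb_p = disp / (disp + mu[None, :] * batch_mult)
        depth = rng.negative_binomial(disp, nb_p)
        depth[rng.random((n, config.n_genes)) < config.dropout] = 0
        for i in range(config.n_genes):
            k = int(ks[i])
            lo, hi = iso_offsets[i], iso_offsets[i] + k
            if k == 1:
                counts[row0 : row0 + n, lo] = depth[:, i]
            else:
                counts[row0 : row0 + n, lo:hi] = rng.multinomial(depth[:, i], usage[p][i])
        row0 += n

    icm = IsoformCountMatrix(list(cell_df.index), iso_ids, counts)
    truth = pd.DataFrame(
        {
            "class": classes,
            "k": ks.astype(int),
            "fold": [config.fold_change if c in _CLASS_POPULATIONS else (config.batch_fold if c == "batch" else np.nan) for c in classes],
            "delta": [config.delta_dif if c == "switch" else np.nan for c in classes],
            "direction": ["up_in_HE_AGM" if c in ("entropy_shift", "switch") else "" for c in classes],
        },
        index=pd.Index(genes, name="gene"),
    )
    # curated "factor" list: all isoform-planted genes plus random others
    iso_genes = [g for g, c in zip(genes, classes) if c in ("entropy_shift", "switch")]
    others = [g for g, c in zip(genes, classes) if c not in ("entropy_shift", "switch")]
    n_extra = max(config.n_factors - len(iso_genes), 0)
    extra = list(rng.choice(others, size=min(n_extra, len(others)), replace=False))
    factors = sorted(iso_genes + extra)

    cell_truth = pd.DataFrame(columns=["violation"], index=pd.Index([], name="cell_id"))
    return SimOutput(icm, gm, CellTable(cell_df), truth, cell_truth, factors, config)


def plant_qc_violations(
    sim: SimOutput,
    n_low_genes: int = 0,
    n_high_mito: int = 0,
    n_high_hb: int = 0,
    n_replicates: int = 0,
    seed: int = 0,
) -> SimOutput:
    """Alter cells so each violates exactly one QC rule; add replicate pairs.

    Designated cells are distinct; replicate pairs duplicate existing intact
    cells with a lower detected-gene count, so deduplication keeps the
    original.  Truth is recorded in ``cell_truth``.
    """
    rng = np.random.default_rng(seed)
    n_needed = n_low_genes + n_high_mito + n_high_hb + n_replicates
    cells = sim.cells.df.copy()
    if n_needed > len(cells):
        raise ValidationError(f"requested {n_needed} designated cells but only {len(cells)} available")
    chosen = list(rng.choice(cells.index.to_numpy(), size=n_needed, replace=False))
    low = chosen[:n_low_genes]
    mito = chosen[n_low_genes : n_low_genes + n_high_mito]
    hb = chosen[n_low_genes + n_high_mito : n_low_genes + n_high_mito + n_high_hb]
    reps = chosen[n_low_genes + n_high_mito + n_high_hb :]

    cells.loc[low, "n_genes_detected"] = rng.integers(800, 2000, size=n_low_genes)
    cells.loc[mito, "pct_mito"] = rng.uniform(15.5, 40.0, size=n_high_mito)
    cells.loc[hb, "pct_hemoglobin"] = rng.uniform(10.5, 30.0, size=n_high_hb)

    truth_rows = [(c, "min_genes") for c in low] + [(c, "max_mito") for c in mito] + [(c, "max_hb") for c in hb]

    icm = sim.icm
    new_rows = []
    new_ids = []
    for i, orig in enumerate(reps):
        group = f"rep{i:03d}"
        twin = f"{orig}_rep"
        cells.loc[orig, "replicate_group"] = group
        twin_row = cells.loc[orig].copy()
        twin_row["replicate_group"] = group
        # keep the twin above the QC floor so it fails only the replicate rule
        twin_row["n_genes_detected"] = int(cells.loc[orig, "n_genes_detected"]) - int(rng.integers(100, 400))
        cells.loc[twin] = twin_row
        new_ids.append(twin)
        new_rows.append(icm.counts[icm.cell_ids.index(orig)])
        truth_rows.append((twin, "replicate"))
    if new_ids:
        icm = IsoformCountMatrix(
            list(icm.cell_ids) + new_ids,
            list(icm.isoform_ids),
            np.vstack([icm.counts] + [r[None, :] for r in new_rows]),
        )
    cell_truth = pd.DataFrame(truth_rows, columns=["cell_id", "violation"]).set_index("cell_id")
    return SimOutput(icm, sim.gene_model, CellTable(cells), sim.gene_truth, cell_truth, sim.factors, sim.config)


def simulate_peaks(
    sim: SimOutput,
    target_genes: Sequence,
    seed: int = 0,
    n_datasets_per_factor: int = 1,
) -> list:
    """Synthetic GFI1/GFI1B peak sets binding the designated target genes.

    Each factor gets ChIP-seq (peaks at the TSS) and/or DamID (peaks at the
    gene body) datasets whose peaks cover exactly ``target_genes``, so the
    multi-dataset target rule has known truth.
    """
    from .peaks import PeakSet

    gm = sim.gene_model
    tss = gm.tss()
    rng = np.random.default_rng(seed)
    out = []
    for factor, assay in (("GFI1", "CHIP"), ("GFI1B", "DAMID")):
        for d in range(n_datasets_per_factor):
            rows = []
            for g in target_genes:
                if assay == "CHIP":
                    center = int(tss.loc[g]) + int(rng.integers(-1000, 1000))
                else:
                    center = int(gm.coords.loc[g, "start"]) + int(rng.integers(0, 2000))
                rows.append((gm.coords.loc[g, "chrom"], max(center - 200, 0), center + 200))
            out.append(PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]),
                               label=f"{factor}_{assay}_{d + 1}", factor=factor, assay=assay))
    return out
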