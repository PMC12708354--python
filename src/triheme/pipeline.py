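"""End-to-end driver: QC -> DE -> shared profile and signatures -> scoring
-> entropy -> dIF -> intersection -> factor filter -> peak targets.

Stage order mirrors the analysis narrative; each stage's randomness is
seeded independently from the single global seed, so stages are
reproducible in isolation.  Outputs are a directory of TSV/JSON files plus
a manifest with the configuration hash and per-output checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, stage_seed
from .de import downsample_equal
from .derive import derive_fate_signatures, derive_shared_profile, filter_factors, interhe_deg
from .diversity import differential_entropy, entropy_matrix, skew_test
from .dtu import dtu_test, intersect_isoform_results, isoform_fractions
from .io import aggregate_to_genes, log_normalize
from .peaks import annotate_peaks, call_targets, intersect_with_profile
from .qc import dedup_replicates, filter_cells, flag_batch_genes
from .scoring import compare_scores, score_matrix
from .simulate import SimConfig, SimOutput, plant_qc_violations, simulate, simulate_peaks
from .types import HE_POPULATIONS, Signature, ValidationError

#: AGM-vs-yolk-sac comparisons used for the skew test and the union list
AGM_VS_YS = (("HE_AGM", "HE_YSP"), ("HE_AGM", "HE_YSA"))
ALL_PAIRS = (("HE_AGM", "HE_YSP"), ("HE_AGM", "HE_YSA"), ("HE_YSP", "HE_YSA"))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(
    config: RunConfig,
    out_dir,
    sim_config: Optional[SimConfig] = None,
    sim: Optional[SimOutput] = None,
) -> dict:
    """Run the full analysis on a synthetic dataset; returns the results dict.

    Either a prepared ``sim`` or a ``sim_config`` (simulated here with the
    run seed) must be provided.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    def _stage(name):
        manifest["stages"][name] = {"seed": stage_seed(config.seed, name)}
        return manifest["stages"][name]["seed"]

    # --- simulate -----------------------------------------------------------
    seed = _stage("simulate")
    if sim is None:
        if sim_config is None:
            sim_config = SimConfig()
        sim_config.seed = seed
        sim = simulate(sim_config)
        sim = plant_qc_violations(sim, n_low_genes=5, n_high_mito=5, n_high_hb=5,
                                  n_replicates=3, seed=stage_seed(config.seed, "plant_qc"))
    manifest["sim_config"] = asdict(sim.config)

    # --- qc -----------------------------------------------------------------
    gcm = aggregate_to_genes(sim.icm, sim.gene_model)
    qc_cells = filter_cells(gcm, sim.cells, config.qc.min_genes, config.qc.max_mito, config.qc.max_hb)
    gcm1 = gcm.subset_cells(qc_cells.retained_cells)
    cells1 = sim.cells.subset(qc_cells.retained_cells)
    qc_dedup = dedup_replicates(gcm1, cells1)
    gcm2 = gcm1.subset_cells(qc_dedup.retained_cells)
    cells2 = cells1.subset(qc_dedup.retained_cells)
    gcm2 = log_normalize(gcm2)
    batch = flag_batch_genes(gcm2, cells2, bridge_population="ENDO_AGM",
                             lfc=config.qc.batch_lfc, padj=config.qc.batch_padj,
                             det_diff=config.qc.batch_det_diff)
    batch_genes = list(batch.excluded_genes.index)
    keep_genes = [g for g in gcm2.gene_ids if g not in set(batch_genes)]
    gcm2 = gcm2.subset_genes(keep_genes)
    icm2 = sim.icm.subset_cells(qc_dedup.retained_cells)
    results["qc"] = {
        "n_input_cells": len(sim.cells.df),
        "n_after_cell_filter": len(qc_cells.retained_cells),
        "n_after_dedup": len(qc_dedup.retained_cells),
        "batch_genes_flagged": batch_genes,
    }

    # --- downsample HE populations to equal sizes ---------------------------
    seed = _stage("downsample")
    he_cells = downsample_equal({he: cells2.cells_of(he) for he in HE_POPULATIONS}, seed=seed)

    ds_cells = cells2.df.copy()
    drop = [c for he in HE_POPULATIONS for c in set(cells2.cells_of(he)) - set(he_cells[he])]
    ds_cells = ds_cells.drop(index=drop)
    cells_ds = cells2.subset(list(ds_cells.index))
    gcm_ds = gcm2.subset_cells(list(ds_cells.index))

    # --- derivation ---------------------------------------------------------
    profile = derive_shared_profile(gcm_ds, cells_ds, lfc=config.de.lfc_universal,
                                    fdr=config.de.fdr, pct=config.de.pct_universal,
                                    max_dropout=config.de.dropout_max)
    inter = interhe_deg(gcm_ds, cells_ds, lfc=config.de.lfc_interhe, fdr=config.de.fdr,
                        pct=config.de.pct_interhe, max_dropout=config.de.dropout_max)
    fate = derive_fate_signatures(gcm_ds, cells_ds, padj=config.de.fdr,
                                  max_dropout=config.de.dropout_max)
    results["shared_profile"] = {
        "n_genes": len(profile.genes),
        "arms": profile.table["arm"].value_counts().to_dict() if len(profile.table) else {},
        "he_restricted": profile.he_restricted,
    }
    results["interhe"] = {"venn": inter["venn"],
                          "up_sets": {k: sorted(v) for k, v in inter["up_sets"].items()}}
    results["fate"] = {"emp_fate": fate.emp_fate, "lmp_fate": fate.lmp_fate}

    # --- scoring ------------------------------------------------------------
    signatures = []
    if profile.he_restricted:
        signatures.append(Signature("HE_restricted", profile.he_restricted))
    if fate.emp_fate:
        signatures.append(Signature("EMP_fate", fate.emp_fate))
    if fate.lmp_fate:
        signatures.append(Signature("LMP_fate", fate.lmp_fate))
    if signatures:
        scores = score_matrix(gcm2, signatures, r_max=config.scoring.r_max)
        pairs = [("PROG_P1", "PROG_P2"), ("EMP", "LMP")]
        comparisons = compare_scores(scores, cells2, pairs)
        results["scores"] = {
            "mean_by_population": scores.groupby(cells2.df["population"]).mean().round(4).to_dict(),
            "comparisons": comparisons.to_dict(orient="records"),
        }
        scores.to_csv(out_dir / "signature_scores.tsv", sep="\t")

    # --- isoform diversity --------------------------------------------------
    em = entropy_matrix(icm2, sim.gene_model, min_total=config.diversity.entropy_min_total)
    entropy_sets: dict = {}
    skews: dict = {}
    for a, b in ALL_PAIRS:
        dc = differential_entropy(em, cells2, [a], [b], diff_min=config.diversity.entropy_diff,
                                  fdr=config.diversity.fdr)
        entropy_sets[f"{a}_vs_{b}"] = set(dc.significant_genes)
        if dc.table["significant"].any():
            st = skew_test(dc)
            skews[f"{a}_vs_{b}"] = {"n_up": st.n_up, "n_down": st.n_down,
                                    "chi2": st.chi2, "p": st.p}
        dc.table.to_csv(out_dir / f"entropy_{a}_vs_{b}.tsv", sep="\t")
    results["diversity"] = {"n_significant": {k: len(v) for k, v in entropy_sets.items()},
                            "skew": skews}

    # --- dtu ----------------------------------------------------------------
    seed = _stage("dtu")
    dtu_sets: dict = {}
    for a, b in ALL_PAIRS:
        ift_a = isoform_fractions(icm2, sim.gene_model, cells2, a, min_total=config.dtu.min_total)
        ift_b = isoform_fractions(icm2, sim.gene_model, cells2, b, min_total=config.dtu.min_total)
        res = dtu_test(ift_a, ift_b, dif_min=config.dtu.dif_min, fdr=config.dtu.fdr,
                       min_if_cells=config.dtu.min_if_cells, n_perm=config.dtu.n_perm, seed=seed)
        dtu_sets[f"{a}_vs_{b}"] = set(res.significant_genes)
        res.isoforms.to_csv(out_dir / f"dtu_{a}_vs_{b}.tsv", sep="\t")
    results["dtu"] = {"n_significant": {k: len(v) for k, v in dtu_sets.items()}}

    # --- intersection and factor filter -------------------------------------
    venn = intersect_isoform_results(entropy_sets, dtu_sets)
    agm_union = set()
    for a, b in AGM_VS_YS:
        agm_union |= venn["comparisons"][f"{a}_vs_{b}"]["union"]
    factor_hits = filter_factors(sorted(agm_union), sim.factors)
    results["isoform_union"] = {
        "n_union_agm_vs_ys": len(agm_union),
        "venn": {k: {kk: vv for kk, vv in v.items() if kk != "union"}
                 for k, v in venn["comparisons"].items()},
        "n_factors": len(factor_hits),
        "factors": factor_hits,
    }

    # --- peak targets -------------------------------------------------------
    seed = _stage("peaks")
    if profile.genes:
        rng = np.random.default_rng(seed)
        n_targets = max(len(profile.genes) // 2, 1)
        target_genes = sorted(rng.choice(profile.genes, size=n_targets, replace=False))
        peaksets = simulate_peaks(sim, target_genes, seed=seed)
        hits = {ps.label: annotate_peaks(ps, sim.gene_model) for ps in peaksets}
        targets = call_targets(hits, {ps.label: ps.factor for ps in peaksets})
        annotated = intersect_with_profile(targets, profile.genes)
        results["targets"] = {
            "n_targets": int(targets["is_target"].sum()),
            "profile_fraction_targets": annotated.attrs["fraction_targets"],
        }

    # --- write bundle -------------------------------------------------------
    (out_dir / "results.json").write_text(json.dumps(results, indent=2, default=str))
    for f in sorted(out_dir.glob("*")):
        if f.name != "manifest.json":
            manifest["stages"].setdefault("outputs", {})
            manifest["stages"]["outputs"][f.name] = _sha256(f)
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
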