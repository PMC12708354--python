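# triheme

Comparative single-cell transcriptome and **isoform-usage** analysis of the
three hemogenic-endothelium (HE) populations of the mouse embryo — the
intra-embryonic HE of the aorta–gonad–mesonephros region (HE^AGM) and the
two extra-embryonic yolk-sac populations (HE^YSA in large arteries, HE^YSP
in the endothelial plexus). These populations sit on parallel
endothelial-to-hematopoietic transition (EHT) trajectories that end,
respectively, in hematopoietic stem/progenitor cells, lymphomyeloid
progenitors (LMPs) and erythromyeloid progenitors (EMPs). The package is
aimed at developmental hematopoiesis groups working with full-length
(Smart-seq2-like) single-cell data, where isoform-level quantification is
possible.

It provides, as a tested and reusable pipeline:

* **QC and batch filtering** — cell quality rules (< 2,000 detected genes,
  > 15% mitochondrial, > 10% hemoglobin content excluded), technical-replicate
  deduplication, a 90% dropout gene filter, and exclusion of
  batch-associated genes detected on a bridge population sequenced in both
  batches (|log2FC| > 1.5 at BH-adjusted p < 0.01, or detection-rate
  difference > 50%).
* **Differential expression** — Wilcoxon rank-sum test on log2
  counts-per-10k values with mean-difference log2FC, Benjamini–Hochberg
  FDR, and expressing-cell fractions.
* **Signature derivation** — the shared HE profile (genes differentially
  expressed in *all three* HEs against the endothelial and/or hematopoietic
  ends of the trajectory, with endothelial-biased / hematopoietic-biased /
  HE-restricted arm labels), pairwise inter-HE DEG sets with Venn
  partition, EMP-fate/LMP-fate signatures by contrast intersection, and a
  k-NN classifier assigning sorted cells to reference clusters.
* **Signature scoring** — per-cell rank-based scores in [0, 1] via a capped
  Mann–Whitney U statistic: with genes ranked by decreasing expression
  (ranks truncated at r_max = 1500),
  `U = Σ rank(g) − n(n+1)/2` and `score = 1 − U / (n·r_max)`.
* **Isoform-usage entropy** — per cell and gene with k annotated isoforms,
  Laplace-smoothed proportions `p_i = (c_i + 1)/(Σc + k)` and normalized
  Shannon entropy `H = −Σ p_i log2 p_i / log2 k`; group comparisons with a
  rank-sum test (significant when |mean difference| > 0.1 and BH p < 0.05)
  and a chi-squared goodness-of-fit test for direction skew.
* **Differential isoform fraction (dIF)** — pooled isoform fractions per
  group, `dIF = IF_A − IF_B`, label-permutation significance, and
  gene-level switch calls (|dIF| > 0.1, BH p < 0.05).
* **Peak-based target annotation** — GFI1/GFI1B binding calls from BED
  peaks (ChIP–seq within 3 kb of the TSS, DamID within 5 kb of the gene
  body), with a gene called a target when bound in at least one GFI1 *and*
  one GFI1B dataset.
* **Synthetic data** — a Dirichlet–multinomial isoform-level generator with
  negative-binomial depth, dropout, and planted ground truth for every
  stage (fold changes, usage-balance shifts, dominant-isoform switches,
  batch genes, QC violations).

## Worked example

Simulate two HE populations in which 50 genes have more balanced isoform
usage in HE^AGM and 25 genes switch their dominant isoform by 0.3, then run
the two isoform-level analyses:

```python
from triheme import (SimConfig, simulate, entropy_matrix, differential_entropy,
                     skew_test, isoform_fractions, dtu_test)

cfg = SimConfig(
    n_cells={"HE_AGM": 100, "HE_YSP": 100}, n_genes=500,
    n_he_restricted=0, n_endothelial_biased=0, n_hematopoietic_biased=0,
    n_emp_fate=0, n_lmp_fate=0, n_interhe_up=0,
    n_entropy_shift=50, n_switch=25, n_batch_genes=0, seed=42)
sim = simulate(cfg)

em = entropy_matrix(sim.icm, sim.gene_model, min_total=10)
dc = differential_entropy(em, sim.cells, ["HE_AGM"], ["HE_YSP"])
st = skew_test(dc)
print(f"entropy: {len(dc.significant_genes)} significant genes "
      f"({st.n_up} up, {st.n_down} down in HE_AGM; chi2={st.chi2:.2f}, p={st.p:.2e})")

ia = isoform_fractions(sim.icm, sim.gene_model, sim.cells, "HE_AGM")
ib = isoform_fractions(sim.icm, sim.gene_model, sim.cells, "HE_YSP")
res = dtu_test(ia, ib, seed=0)
print(f"dIF: {len(res.significant_genes)} switch genes")
```

prints

```
entropy: 63 significant genes (50 up, 13 down in HE_AGM; chi2=21.73, p=3.14e-06)
dIF: 73 switch genes
```

All 50 planted entropy shifts are recovered and the direction skew toward
HE^AGM is highly significant; the 13 "down" genes and the extra dIF calls
are planted switch genes, whose usage change is real but direction-mixed —
the two analyses intentionally capture overlapping gene sets. The
per-isoform table shows the planted switches recovered at their planted
magnitude (`dIF ≈ ±0.30`, BH p < 0.01).

The same analyses are available from the shell:

```sh
triheme simulate --seed 5 --out-dir fixtures/
triheme diversity --matrix fixtures/counts.mtx --isoforms fixtures/isoforms.tsv \
    --cells fixtures/cells.tsv --annotations fixtures/annotations.tsv \
    --gene-model fixtures/genes.gtf --a HE_AGM --b HE_YSP --out-dir out/
triheme run --simulate --seed 0 --out-dir run_out/   # full pipeline
```

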