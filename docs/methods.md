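# Methods

This note documents the statistical models and procedures implemented in
`triheme`, the defaults they use, and the choices made where the design was
genuinely open.

## Normalization and differential expression

Gene counts are the per-cell sum of their isoforms' estimated counts.
Normalization is counts-per-10k on a log2 scale,
`v = log2(1 + 10^4 · c / cell_total)`; the scale factor and base are
package conventions chosen so downstream effect sizes read directly as
log2 fold changes. Zero counts map to zero and the transform is monotone
within a cell, which is all the rank-based statistics below require.

The DE engine is deliberately simple and fully specified: a two-sided
Wilcoxon rank-sum (Mann–Whitney U) test on the normalized values, with
log2FC defined as the difference of group means on the normalized scale.
For pooled samples of at most 12 values (or whenever a group has fewer
than 3 cells), the p-value comes from exhaustive enumeration of all
C(n, n_A) group labelings — exact under ties; otherwise a tie- and
continuity-corrected normal approximation is used. Multiplicity is
controlled with the Benjamini–Hochberg step-up rule
(`q_(i) = min_{j≥i} p_(j)·m/j`, capped at 1). Genes with more than 90%
zero-count cells across a contrast are excluded before testing. Quasi-
likelihood or precision-weighted linear models would add power on real
data but obscure the thresholding behaviour that drives every downstream
set construction; all the package's conclusions are threshold-set based,
and the engine's calibration is verified directly (null p-values uniform
by Kolmogorov–Smirnov; essentially zero BH discoveries on null
simulations).

Thresholds (all configurable in `RunConfig`, defaults as used throughout):

| stage | rule |
|---|---|
| cell QC | fail if detected genes < 2,000, mito > 15%, or hemoglobin > 10% (strict, boundary passes) |
| replicate dedup | keep the replicate with most detected genes; ties → lexicographically smallest cell id |
| dropout filter | exclude genes with > 90% zero cells over the contrast |
| batch genes | within the bridge population: \|log2FC\| > 1.5 & BH p < 0.01, or detection-rate difference > 50% |
| shared profile | expressed in ≥ 33% of each HE's cells; \|log2FC\| > 1 & BH p < 0.05 vs ≥ 1 trajectory end in **all three** HEs |
| inter-HE DEGs | log2FC > 1.5, BH p < 0.05, expressed in > 50% of the upregulated population |
| fate signatures | BH p < 0.05 in both intersected contrasts |
| entropy | \|mean difference\| > 0.1 & BH p < 0.05; cells with gene total < 10 undefined |
| dIF | \|dIF\| > 0.1 & BH p < 0.05; ≥ 10 qualifying cells per group |

## Shared-profile arms and fate signatures

Per HE population, two contrasts are run: against its nearest endothelium
(HE^AGM → AGM endothelium; both yolk-sac HEs → yolk-sac endothelium) and
against the pooled EMP+LMP hematopoietic end. A gene enters the profile if
it passes at least one end-contrast in every HE with a direction pattern
consistent across HEs ("in all three HEs" is the default reading of a
*shared* profile; `require_all_hes=False` gives the permissive variant for
sensitivity analysis). Arms: genes up versus *both* ends in all HEs are
HE-restricted; otherwise genes whose expression is higher toward the
endothelial end (down in HE vs endothelium, or up vs the hematopoietic
end) are endothelial-biased, and the mirror pattern is
hematopoietic-biased. A gene passing both contrasts downward (a "valley")
is assigned by the larger effect; such genes do not arise in the planted
simulations.

Fate signatures intersect EMP-vs-LMP with progenitor p2-vs-p1 at
BH p < 0.05, pairing directions so that p2 resembles EMP and p1 resembles
LMP.

The k-NN classifier standardizes the reference's normalized expression,
fits a 50-component PCA (capped at n_ref − 1), projects queries, and takes
the majority label among the k = 10 Euclidean nearest reference cells;
vote ties go to the label with the smallest summed distance. The metric
and embedding are package choices — any reasonable low-dimensional
Euclidean embedding gives the same assignments on well-separated clusters,
which is the regime the classifier is used in.

## Signature scoring

The per-cell score is a capped Mann–Whitney U statistic on the cell's
expression ranking: ranks by decreasing expression with average ranks for
ties (undetected genes share tied bottom ranks), truncation of ranks
beyond r_max = 1500 to r_max + 1, and for an n-gene signature
`score = 1 − (Σ ranks − n(n+1)/2) / (n·r_max)`, clipped to [0, 1]. The
score is 1 when the signature occupies the top n ranks and 0 when a
single-gene signature falls beyond r_max (multi-gene signatures floor at
`(n−1)/(2·r_max)` by construction). Being rank-based, it is invariant to
monotone transforms of expression, so the normalization constants above do
not affect it. Group comparisons of scores use the same rank-sum test and
BH correction as the DE engine.

## Isoform-usage entropy

For a gene with k annotated isoforms and per-cell isoform counts c_i,
usage proportions are Laplace-smoothed, `p_i = (c_i + 1)/(Σc + k)`, and
the normalized Shannon entropy is `H = −Σ p_i log2 p_i / log2 k ∈ [0, 1]`.
Smoothing over the *annotated* isoform set penalizes low totals: a pure
single-isoform gene approaches 0 monotonically as depth grows, and H = 1
exactly iff the smoothed proportions are uniform. Cells with gene total
below `min_total = 10` and single-isoform genes are undefined and excluded;
genes need ≥ 3 defined cells per group to be tested. Entropy is computed
per cell and averaged per group (the package's reading of a "mean entropy
difference"); a pooled-abundance mode would be a one-line variant but is
not the default. Group differences use the two-sample rank-sum test — a
paired (signed-rank) test is not applicable to independent cell groups —
with BH correction, and the direction skew of significant genes is tested
with a 1-df chi-squared goodness-of-fit statistic against a 50:50 split.

## Differential isoform fraction

Pooled isoform fractions per group are `IF_i = Σ_cells c_i / Σ_cells
gene_total` over qualifying cells (gene total ≥ 10), so a gene's IFs sum
to 1 per group and dIFs sum to 0. Significance per isoform comes from a
two-sided label-permutation test of the pooled dIF (1,000 permutations,
add-one correction `p = (b + 1)/(n_perm + 1)`, seeded), BH-adjusted across
all tested isoforms. The permutation engine replaces a quasi-binomial GLM:
it is assumption-light, exactly specified, and its calibration is verified
on null simulations (significant-gene fraction within the binomial
envelope of the FDR level). With 1,000 permutations the smallest
attainable p is ~1e-3, ample for the |dIF| > 0.1 conjunction rule at the
scales this package targets.

## Peak-based target annotation

ChIP–seq peaks hit a gene when the nearest peak edge lies within 3 kb of
the transcription start site (TSS = gene start on +, end − 1 on −); DamID
peaks when within 5 kb of the gene body. Distances are edge-to-edge on the
genomic continuum (overlap = 0) with inclusive boundaries. A gene is a
GFI target when bound in at least one GFI1 and one GFI1B dataset. Hit
calls are set-valued per dataset, hence invariant to peak order and
duplication.

## Synthetic data generator

The generator emulates full-length (Smart-seq2-like) single-cell isoform
quantification across nine populations (two endothelia, three HEs, two
early progenitor clusters, EMPs and LMPs; 100 cells each by default):

* **Depth** — per gene-cell negative binomial with mean
  `μ = 100 × lognormal(0, 0.5)` per gene and dispersion 2
  (variance = μ + μ²/dispersion), zeroed with dropout probability 0.15.
  The low dropout reflects full-length libraries (~6,500 genes detected
  per cell); higher dropout shrinks mean-difference log2FCs below the
  fixed thresholds and breaks the correspondence between planted truth and
  detectable effect.
* **Usage** — isoform multiplicity k drawn from a categorical distribution
  over 1–8 (25% single-isoform); a usage vector π ~ Dirichlet(α·1_k) drawn
  **once per gene** and shared by all cells of all populations, so
  non-planted genes are true nulls for both isoform-level tests. Cells
  split their gene depth Multinomial(depth, π).
* **Planted classes** — expression classes multiply μ in designated
  populations (fold 6 by default, so planted markers clear the log2FC
  thresholds by construction; the DE-calibration analyses use fold 4 with
  the log2FC > 1 rule): HE-restricted (up in all three HEs),
  endothelial-biased, hematopoietic-biased, per-HE markers, EMP/LMP-fate
  pairs, and batch genes (fold 8 tied to the sequencing batch, not to any
  population, with the AGM endothelium split across batches as the
  bridge). Usage classes give HE^AGM either a balanced draw
  (α = 5, high entropy) against a dominant-isoform draw elsewhere
  (α = 0.2), or a switch transferring δ = 0.3 of usage mass between the
  top two isoforms (the planted pooled dIF).
* **QC truth** — cell metrics (detected genes ~ N(6553, 800), mito and
  hemoglobin percentages) are generated as annotations at real-data scale
  rather than computed from the 2,000-gene matrix, so the absolute QC
  thresholds are meaningful; `plant_qc_violations` makes designated cells
  violate exactly one rule each and adds technical-replicate twins with
  lower detected-gene counts.

What the generator does **not** model: fragment-level coverage biases,
gene length effects, ambient RNA, doublets, cell-to-cell usage
heterogeneity within a population, or correlated gene programs. Passing
tests therefore demonstrate that the statistics recover the planted
structure under the assumed noise model at the stated sizes — not that
they would achieve the same sensitivity on real Smart-seq2 data, where
per-cell usage jitter and quantification uncertainty add variance the
Dirichlet–multinomial population model does not carry.

## Problem sizes and numerical choices

The default end-to-end run uses 2,000 genes and 9 × 100 cells and
completes in about half a minute on one CPU; the calibration analyses use
1,000–2,000 genes and 100 cells per group with seeds fanned out
deterministically per stage (`stage_seed`). Degenerate inputs are defined
errors rather than silent results: empty groups, zero-total cells at
normalization, signatures absent from the universe, coordinate-free gene
models at peak annotation, and a skew test with no significant genes all
raise. Constant columns in the rank-sum test return p = 1 (no evidence),
and permutation p-values are floored by the add-one rule, keeping every
reported p in (0, 1].

## Known limitations

* The mean-difference log2FC on log-normalized values underestimates raw
  fold changes in the presence of dropout; thresholds are calibrated to
  this scale, not to raw fold changes.
* The permutation dIF test's resolution is bounded by n_perm; very small
  effects on very large cell numbers would need more permutations.
* The shared-profile arm labels are a discrete summary of a continuous
  expression trajectory; genes near the thresholds can change arm under
  resampling.
* The entropy statistic conditions on annotated isoform multiplicity k;
  it is not comparable between genes with different k, only between
  groups for the same gene.
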