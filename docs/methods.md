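# Methods

This note documents the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic data emulate (and do not), and the
numerical conventions and known limitations.

## Quality control

Cells are kept iff they detect ≥ `min_genes_per_cell` (500) genes with at
least one read and carry ≥ `min_counts_per_cell` (50,000) total reads after
subtracting the 45S pre-ribosomal RNA gene (*Rn45s*), both bounds inclusive.
The rRNA gene is subtracted from the total-count criterion only, and is then
dropped from the analysis entirely (it is uniformly overabundant and
uninformative). Genes are kept iff they reach count ≥ 5 in ≥ 5 *retained*
cells — the cell filter runs first because gene detection is defined over
surviving cells — and do not lie on chromosome Y. QC is idempotent.

## Dropout imputation

Plate-based scRNA-seq zeroes are a mix of biological silence and technical
failure to capture transcripts. The imputer distinguishes them per gene and
subpopulation:

* cells are clustered into `n_subpops` subpopulations by spectral clustering
  on the top-20 principal components of scaled log counts, with a Gaussian
  affinity at the median-pairwise-distance bandwidth;
* per gene per subpopulation, scaled log expression
  v = ln(count/total·10⁴ + 1.01) is modelled as λ·Gamma(α, β) +
  (1−λ)·Normal(μ, σ) by EM. The Gamma is the dropout component; its mean is
  capped at 1.0 scaled-log units (≈ counts at the detection floor) so it
  cannot annex the lower half of a genuinely unimodal expression
  distribution — without the cap, EM happily splits any unimodal law in
  two. Gamma updates use weighted moment matching; non-convergent fits fall
  back to λ = 0 and are flagged;
* the per-entry dropout probability is the posterior of the Gamma component;
  entries with d > 0.5 (the `dropout_threshold`) are re-estimated by
  non-negative least squares of the cell on its 10 most similar
  same-subpopulation cells, fitted only on the cell's confident genes
  (d ≤ 0.5), and mapped back to the counts scale. Entries at or below the
  threshold are never modified.

Imputation quality is assessed by per-gene maximum-likelihood negative
binomial fits (profile likelihood over the dispersion by bounded search) to
the raw and imputed matrices. For tight, well-expressed genes an excess of
technical zeros is irreconcilable with a single NB, so restoring them raises
the likelihood; for strongly overdispersed genes a zero-inflated sample can
have *higher* raw likelihood (mass concentrated at zero), so the comparison
is informative mainly in the moderately-to-highly expressed regime.

## Normalization and cell validation

Log normalization is v = ln(count/total·scale + 1) with scale 10⁴. Batch
correction finds mutual k-nearest-neighbour pairs (k = 20) between
cosine-normalized batches, takes per-pair difference vectors on the log
scale, and shifts each incoming cell by a Gaussian-kernel-weighted average
of pair vectors (bandwidth = median pair distance); batches merge
sequentially into a growing reference. Because the kernel smooths over
neighbouring pairs, corrections on identical batches are small but not
exactly zero, and batch order changes results within a small tolerance.

HVGs are genes whose log dispersion ln(var/mean), z-standardized within 20
equal-frequency mean bins, exceeds 0.5, with mean expression strictly inside
(0.0125, 3). The embedding-consistency filter embeds HVG-space PCs (50) into
2-D by t-SNE (perplexity 30) with `reps` = 5 different seeds and removes
cells whose nearest neighbour carries a different cell-type label in a
majority of repetitions; a mislabelled cell can drag its immediate
neighbour along, which is accepted. Library-size balance between the sexes
is checked per cell type with a two-sample KS test.

## Differential-distribution classification

Per gene, a two-sample KS test on normalized values (zeros included)
compares the sexes; p-values are BH-adjusted across genes within the cell
type ("Bonferroni-Hochberg" in common usage equates to Benjamini–Hochberg
when FDR is meant, and FDR is what the thresholds refer to). Genes with
FDR ≥ 0.05 are NS. For significant genes, the modality of log nonzero
expression per sex is chosen between 1- and 2-component Gaussian mixtures by
BIC — a deterministic finite-mixture surrogate for a Dirichlet-process
partition, justified because every category definition only consumes
modality ∈ {1, 2}. Numerical conventions:

* variance ridge `reg_covar` = 0.04 (sd floor 0.2 log-units): low counts
  are discrete on the log scale, and without the floor near-duplicate
  values form spurious zero-width modes;
* fewer than 10 nonzero values → modality 1 with a low-confidence flag;
* components are ordered by mean; two components "overlap" when their means
  differ by at most one pooled standard deviation (one pooled sd is the
  package's own tolerance choice);
* DP requires matched component means in both sexes plus a two-proportion
  z-test on hard component assignments at p < 0.05.

DE candidates (both sexes unimodal) are finalized iff the gene's KS FDR lies
within the smallest 3% of all tested genes — implemented as
FDR ≤ quantile(FDR, 0.03), inclusive of ties — **and** the absolute
difference in log₁₀ library-size-scaled mean expression strictly exceeds
0.2 (≈ 1.5-fold; means are guarded by ε = 1/max library size against empty
genes). Candidates failing either gate become NC.

DZ is assessed on an orthogonal channel: logistic regression of the
zero-indicator on sex plus each cell's detection rate (the proportion of
expressed genes), with a likelihood-ratio χ²(1) test of the sex term,
BH-adjusted, called at FDR < 0.025. Fitting uses binomial IRLS, which
degrades gracefully under separation. A gene can be DZ *and* carry a shape
category: a strong mean shift also shifts dropout rates, so DE/DB genes are
often additionally DZ — this is by construction, not misclassification.
"DD genes" are the union of DM, DP, DB, DZ and NC.

## Per-cell pathway scores

For each gene, expression is transformed to a Gaussian-kernel CDF across
cells (bandwidth sd·n^(−1/5); constant genes map to 0.5 — the kernel is
Gaussian because inputs are continuous log values). Per cell, genes are
ranked by the CDF value and given the symmetric rank statistic |p/2 − rank|.
Each set's score is a weighted KS-like random walk over the ranking (weight
exponent τ = 1), with the signed maximum-deviation-difference statistic:
ES = max positive deviation + max negative deviation, bounded in [−1, 1]. A
set spanning all genes carries no discrimination and scores 0 by convention.
Sets with fewer than 5 present genes are excluded. Between-sex comparison is
Welch's *t* per set with BH across sets; significance needs FDR < 5·10⁻⁵
and |mean difference| > 0.1.

Per-cell GSEA (used for the housekeeping/cell-cycle check) ranks genes by
normalized expression, weights by expression (exponent 1), and normalizes
the ES by the mean |ES| of same-sign gene-label permutations. Each cell
draws an **independent** permutation panel: a single shared panel couples
its random overlap with particular gene identities to every cell the same
way, and that shared bias produced measurable false positives (10% of
nominally null between-group Welch tests below p = 0.01) before the change.

## Sub-cell-type discovery

The imputed (not normalized) matrix restricted to DD genes is re-normalized
de novo; HVGs are selected with the standard thresholds; PCA (centered, not
scaled — scaling would let near-constant genes dominate) retains PCs
explaining > 2% of variance each (floor of 2). A kNN graph (k = 20) in PC
space becomes a shared-nearest-neighbour graph with Jaccard edge weights
(neighbour sets include the cell itself; edges with weight ≤ 1/15 pruned),
clustered by Louvain modularity optimization (RB-configuration null model)
at resolution 0.3, seeded and relabelled by size for determinism. Markers
come from two-sided Wilcoxon rank-sum tests over genes expressed in ≥ 25%
of either population, BH-adjusted, sorted by (FDR, p, |effect|) — the
effect (difference of mean log expression) breaks ties because Wilcoxon p
saturates at its resolution for strongly separated groups. Composition
flags clusters with > 90% of one sex as sex-dominated.

## Regulatory networks

Promoter windows are (−750, +250) bp around the TSS of single-TSS genes and
(−1000, +500) around the floor-midpoint of double-TSS genes, mirrored on
the minus strand (strand orientation is the package's choice; coordinates
are stored 1-based inclusive); genes with ≥ 3 distinct TSSs are dropped,
windows clipped at position 1 are flagged.

PWM scanning scores both strands by summed log₂ odds against the background
(default uniform 0.25 with pseudocount 0.1 on the motif probabilities). The
score-to-p map is the exact distribution of window scores under the iid
background, built by dynamic programming whose partial sums accumulate in
scan order — so for motifs up to length 12 the p-values are bit-identical to
brute-force enumeration; longer motifs merge states by rounding partial
sums to 1e-6. Windows containing N are skipped; hits need p < 5·10⁻⁵. The
motif prior keeps genes that are moderately expressed, autosomal, have a
promoter window and at least one hit; TFs on sex chromosomes are kept, TFs
with no hits are dropped.

PANDA normalizes the motif prior, the TF–TF interaction matrix and the gene
coexpression matrix so each entry is the average of its row- and column-
z-scores scaled by 1/√2, then iterates the continuous-Tanimoto message
passing: responsibility R = T(P, W), availability A = T(W, C),
W ← (1−α)W + α(R+A)/2 with α = 0.1, refreshing P and C from W with
diagonal damping, until the mean update magnitude falls below 10⁻³ (cap 200
iterations; non-convergent runs are returned with a warning flag). With
α = 0 the output equals the normalized prior. Coexpression is Pearson
across cells with constant genes assigned correlation 0 off-diagonal.

Jackknife ensembles draw, per sex, `n_networks` (100) independent subsets
of `cells_per_network` (10) cells without replacement within a subset,
compute subset coexpression and infer one network each. Differential edges:
Welch's *t* per edge on the 100-vs-100 Z-scores, discarding edges with
negative mean in both ensembles, BH over the rest, significant at
FDR < 5·10⁻⁵ with |Δmean| > 0.25. Differential degrees: active edges have
positive mean in ≥ 1 ensemble; out-degree (per TF) and in-degree (per gene)
sum active-edge weights per network; Welch + BH, significant at FDR < 0.05
with |Δ| > 10 (the threshold is absolute and scales implicitly with network
size; it is exposed in the configuration).

**Pseudo-replication caveat.** All networks of one ensemble resample the
same finite cell population, so they are not independent replicates: chance
population-level coexpression differences set a floor on |Δmean Z| that
does not shrink as the ensemble grows, and the per-edge Welch tests are
anti-conservative with respect to the population level. On synthetic data
this shows up as seed-to-seed variability of the planted-edge ranking AUC
(observed 0.74–0.94 across seeds at the default signal strength) and as an
occasional single "significant" edge under a stratified sex-permutation
null. Conclusions about individual edges should therefore lean on the
effect-size gate as much as the FDR.

## Enrichment

Each term is a Fisher's exact test on the 2×2 table of (in list) × (in
term) within the declared background; gene lists must be subsets of the
background (violations are an error, not a silent drop). GO mode reports
raw p ranked ascending without multiplicity correction — nested GO terms
are not independent — and calls p < 0.05 with overlap ≥ 5; KEGG mode
applies BH and calls FDR < 0.1 with overlap ≥ 5.

## Synthetic data: what it emulates, and what it does not

`simulate_expression` draws NB counts (variance μ + μ²/θ) with
log μ = gene base + cell-type offset + per-category sex effect + batch
offset + log library factor, followed by technical dropout
(Bernoulli with probability σ(intercept − slope·ln(1+μ))) and, for DZ
genes, sex-specific structural zeros. Raw-data defaults: θ = 3 and dropout
intercept 0.5/slope 1.0 (moderate plate-based dropout); library factors are
drawn identically for both sexes. Category generators: DE = ±2.5 log-unit
shift (~12-fold — DE genes are by definition the most extreme KS signals in
the transcriptome, and canonical sex-dimorphic genes are near-binary);
DM = mixture of the base component (shared) and base + 2.0; DP = components
{base, base + 2.0} with proportions 0.8/0.2 swapped between the sexes;
DB = components base ± 1.5 in one sex versus unimodal base in the other
(no shared component); DZ = +0.45 structural-zero probability in one sex.
Two structural choices matter at desk scale:

* effects are planted on moderately expressed genes (base above the 30th
  percentile) — distributional categories are undefined at the detection
  floor — and extra mixture components sit above base, because a downward
  component is eroded by dropout and stops being an identifiable mode;
* planted effects come in base-sharing pairs with the affected sex
  alternating. A multiplicative effect is one-sided in count space (+2.5
  logs adds ~11× a gene's counts; −2.5 removes at most 1×), so unpaired
  planting skews total library size between the sexes and library-size
  normalization then leaks a compositional shift into every null gene. A
  15,000-gene transcriptome dilutes this artifact ~15-fold relative to a
  1,000-gene panel; pairing removes it by construction.

The DD-recovery validation draws its counts in the post-imputation regime
(θ = 10, dropout intercept −1.5): the classifier operates on imputed data
in the full pipeline, and that is the input whose recovery the validation
measures. Null-calibration runs use the raw-data defaults.

`simulate_regulation` draws iid N(0,1) per-cell TF activities; each TF's
targets receive β·activity in log mean with β = 1 (TF00 only in females,
TF01 only in males, the rest in both sexes). The motif prior holds all
planted edges plus 5× random decoys; the PPI groups TFs into pairs with
within-family score 0.8. The sub-state scenario plants two biological
programs per sex with heterogeneous per-gene effect sizes, mirrored F/M
signature parameters (so matched cross-sex clusters are exchangeable for
the housekeeping check) and program effects dominating sex effects, as in
sex-dimorphic sub-states of a shared lineage.

Not emulated: UMI chemistry, ambient RNA, doublets, gene-length effects,
transcriptome-scale gene panels, realistic TF-network topology, or
correlated TF activities. Passing the synthetic validations therefore
demonstrates correctness of the algorithms under the stated generative
assumptions, not performance on any particular real tissue.

## Validation scales

The validation scenarios use 1,000 genes at 100 cells/sex with 20 planted
genes per category (DD recovery and null calibration), 10 TFs × 200 genes
at 150 cells/sex with 100+100 jackknife networks of 10 cells (network
recovery), and 4 × 75 cells over a 200-gene panel (sub-state recovery) —
sizes at which every scenario completes in seconds to tens of seconds on a
single CPU while keeping the per-category counts large enough for stable
sensitivity estimates.
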