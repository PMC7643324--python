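# scdimorph

Sex-dimorphic gene expression analysis for single-cell RNA-seq.

Most differential-expression tools compare group means. In single-cell data,
sex differences often appear instead as changes in the **shape** of a gene's
expression distribution: a second expression mode present in one sex, the
same two modes occupied in different proportions, or an excess of true zeros.
`scdimorph` implements a multi-level pipeline for detecting and dissecting
such differences between female (F) and male (M) cells of one cell type:

1. **QC** — cells need ≥ 500 detected genes and ≥ 50,000 reads after
   subtracting the overabundant 45S pre-rRNA (*Rn45s*); genes must reach
   count ≥ 5 in ≥ 5 cells; chrY genes are removed.
2. **Dropout imputation** — cells are spectrally clustered into
   subpopulations; each gene's scaled log expression is modelled per
   subpopulation as λ·Gamma + (1−λ)·Normal, where the Gamma component
   absorbs technical-dropout mass near the detection floor; entries with
   posterior dropout probability *d* > 0.5 are re-estimated by non-negative
   regression on the cell's most similar neighbours. A per-gene negative
   binomial likelihood comparison quantifies the improvement.
3. **Normalization** — log library-size normalization
   (ln(count/total·10⁴ + 1)) with mutual-nearest-neighbour batch correction,
   highly-variable-gene selection (standardized log dispersion > 0.5, mean
   in (0.0125, 3)), an embedding-consistency cell filter and a
   library-size balance check between the sexes.
4. **Differential distribution (DD) classification** — per gene, a
   two-sample Kolmogorov–Smirnov screen (BH FDR < 0.05) followed by
   1-vs-2-component Gaussian-mixture modality fits of log nonzero
   expression, yielding the categories
   **DE** (both unimodal; KS FDR in the smallest 3% and
   |Δlog₁₀ mean| > 0.2 ≈ 1.5-fold), **DM** (modality differs, one shared
   component), **DB** (modality differs, no shared component), **DP** (same
   two components, different mixing proportions), **DZ** (differential
   proportion of zeros by logistic regression with a detection-rate
   covariate, χ² FDR < 0.025) and **NC** (significant but uncategorizable).
5. **Per-cell pathway scores** — GSVA-style Kolmogorov–Smirnov-like random
   walk scores per gene set per cell over the DD genes; Welch's *t* between
   sexes with FDR < 5·10⁻⁵ and |Δscore| > 0.1.
6. **Sub-cell types** — de-novo renormalization of the DD genes, PCA (PCs
   explaining > 2% variance each), shared-nearest-neighbour Louvain
   clustering at resolution 0.3, Wilcoxon markers (≥ 25% detection,
   FDR < 0.05), per-cluster sex composition, and a per-cell GSEA sanity
   check that housekeeping genes show no sex difference.
7. **Regulatory networks** — promoter windows around annotated TSSs
   ((−750, +250) for single-TSS genes, (−1000, +500) around the midpoint of
   two), FIMO-style PWM scanning with exact score-distribution p-values
   (p < 5·10⁻⁵) to build a binary TF×gene motif prior, then **PANDA**
   message passing integrating the prior with TF–TF interactions and gene
   coexpression. Jackknife ensembles (100 networks of 10 random same-sex
   cells per condition) feed Welch tests of per-edge Z-scores
   (FDR < 5·10⁻⁵, |ΔZ| > 0.25) and of active-edge out-/in-degree sums
   (FDR < 0.05, |Δ| > 10).
8. **Enrichment** — Fisher's exact overlap tests against GMT annotations
   (GO mode: p < 0.05 and overlap ≥ 5, ranked without multiplicity
   correction; KEGG mode: BH FDR < 0.1 and overlap ≥ 5).

A synthetic-data module (`scdimorph.simdata`) generates negative-binomial
count matrices with technical dropout, planted DD genes of every category,
and a latent TF-activity model with sex-specific regulatory strength — plus
motif/promoter/PPI fixtures — so the whole pipeline is testable end to end
with known ground truth.

## Worked example

```python
import pandas as pd
from scdimorph.simdata import SimConfig, simulate_expression
from scdimorph.preprocess import lognormalize
from scdimorph.diffdist import run_diffdist

cfg = SimConfig(
    n_genes=400, n_cells_per_sex=100,
    category_counts={"DE": 8, "DM": 8, "DP": 8, "DB": 8, "DZ": 8},
    nb_dispersion=10.0, dropout_intercept=-1.5, seed=1,
)
counts, truth = simulate_expression(cfg)
normalized = lognormalize(counts)
table = run_diffdist(normalized, counts, seed=1)

print(table["category"].value_counts().to_string())
print("DZ genes:", int(table["is_DZ"].sum()))
print(pd.crosstab(truth.genes["dd_category"], table["category"]).to_string())
```

Output:

```
category
NS    358
NC     10
DM      8
DB      8
DE      8
DP      8
DZ genes: 15
category     DB  DE  DM  DP  NC   NS
dd_category
DB            8   0   0   0   0    0
DE            0   8   0   0   0    0
DM            0   0   8   0   0    0
DP            0   0   0   8   0    0
DZ            0   0   0   0   8    0
NS            0   0   0   0   2  358
```

All 40 planted genes are recovered in their correct category (the 8 planted
DZ genes are flagged through the orthogonal zero-proportion channel and
appear as NC in the shape column, as their nonzero distributions are
identical by construction; the extra DZ flags sit on planted shape genes
whose expression change also shifts their dropout rate). Two of 360 null
genes (0.6%) are called significant.

There is also a thin CLI over the same functions:

```bash
scdimorph simulate --out fixtures --seed 1
scdimorph preprocess --counts fixtures/counts.mtx --meta fixtures/cells.meta.tsv --out pre
scdimorph diffdist --norm pre/normalized.tsv --counts pre/imputed.mtx \
    --meta pre/imputed.meta.tsv --out dd.tsv
scdimorph pathscore --norm pre/normalized.tsv --meta pre/imputed.meta.tsv \
    --gmt fixtures/sets.gmt --dd dd.tsv --out pathways
scdimorph regnet --norm pre/normalized.tsv --meta pre/imputed.meta.tsv \
    --prior motif.tsv --ppi fixtures/ppi.tsv --out networks --seed 1
```

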