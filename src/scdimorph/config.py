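"""Analysis-wide configuration.

Every numeric threshold used by the pipeline lives here as a named,
overridable field so that a single object documents the analysis settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class AnalysisConfig:
    """All tunable constants of the sex-dimorphism pipeline.

    Defaults reproduce the published analysis settings: cells need >= 500
    detected genes and >= 50,000 post-rRNA counts, genes must be moderately
    detected (count >= 5) in >= 5 cells, differential-distribution calls use
    an FDR < 0.05 screen, DE genes additionally need a KS FDR in the smallest
    3% and a log10 mean difference > 0.2 (~1.5-fold), pathway calls use
    FDR < 5e-5 with |score difference| > 0.1, and network comparisons use
    100+100 jackknife PANDA networks of 10 cells each.
    """

    # QC
    min_genes_per_cell: int = 500
    min_counts_per_cell: int = 50_000
    gene_detect_count: int = 5
    gene_detect_cells: int = 5
    rrna_gene: str = "Rn45s"

    # imputation
    dropout_threshold: float = 0.5

    # HVG selection
    hvg_dispersion: float = 0.5
    hvg_mean_lo: float = 0.0125
    hvg_mean_hi: float = 3.0

    # embedding consistency
    tsne_perplexity: float = 30.0
    tsne_reps: int = 5

    # differential distribution
    dd_fdr: float = 0.05
    de_fdr_quantile: float = 0.03
    de_log10_diff: float = 0.2
    dz_fdr: float = 0.025

    # pathway scoring
    gsva_fdr: float = 5e-5
    gsva_diff: float = 0.1

    # sub-cell-type discovery
    pc_var_frac: float = 0.02
    cluster_resolution: float = 0.3
    marker_min_pct: float = 0.25
    marker_fdr: float = 0.05

    # motif scanning / promoters (bp offsets relative to the TSS / midpoint)
    pwm_pval: float = 5e-5
    promoter_single: tuple[int, int] = (-750, 250)
    promoter_double: tuple[int, int] = (-1000, 500)

    # jackknife PANDA ensembles
    n_networks: int = 100
    cells_per_network: int = 10
    panda_alpha: float = 0.1
    panda_tol: float = 1e-3
    panda_max_iter: int = 200
    edge_diff: float = 0.25
    edge_fdr: float = 5e-5
    degree_diff: float = 10.0
    degree_fdr: float = 0.05

    # enrichment
    go_p: float = 0.05
    go_min_overlap: int = 5
    kegg_fdr: float = 0.1

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.de_fdr_quantile <= 1):
            raise ValueError("de_fdr_quantile must lie in (0, 1]")
        for name in (
            "min_genes_per_cell",
            "min_counts_per_cell",
            "gene_detect_count",
            "gene_detect_cells",
            "dd_fdr",
            "dz_fdr",
            "gsva_fdr",
            "gsva_diff",
            "edge_diff",
            "edge_fdr",
            "degree_diff",
            "degree_fdr",
            "pwm_pval",
            "n_networks",
            "cells_per_network",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
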