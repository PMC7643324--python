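"""Overlap-based functional enrichment of gene lists.

Each annotation term is tested by Fisher's exact test on the 2x2 table of
(in list) x (in term) within the declared background.  GO mode ranks terms
by raw p (no multiplicity correction: nested GO terms are not independent)
and calls significance at p < 0.05 with overlap >= 5; KEGG mode applies BH
across terms and calls FDR < 0.1 with overlap >= 5.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .datatypes import GeneSetCollection
from .stats import bh_fdr, fisher_exact

__all__ = ["enrich_genesets"]


def enrich_genesets(
    gene_list,
    annotations: GeneSetCollection,
    background,
    mode: str = "go",
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-term Fisher's exact enrichment of ``gene_list`` vs ``background``."""
    if mode not in ("go", "kegg"):
        raise ValueError("mode must be 'go' or 'kegg'")
    cfg = cfg or AnalysisConfig()
    bg = set(background)
    genes = set(gene_list)
    outside = genes - bg
    if outside:
        raise ValueError(f"genes absent from background: {sorted(outside)[:5]}")
    rows = []
    for name, members in annotations.sets.items():
        term = set(members) & bg
        if not term:
            continue
        a = len(genes & term)
        b = len(genes - term)
        c = len(term - genes)
        d = len(bg) - a - b - c
        p = fisher_exact([[a, b], [c, d]])
        rows.append(
            {
                "term": name,
                "overlap": a,
                "list_size": len(genes),
                "term_size": len(term),
                "background": len(bg),
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    if mode == "go":
        out["fdr"] = np.nan
        out["significant"] = (out["p"] < cfg.go_p) & (out["overlap"] >= cfg.go_min_overlap)
    else:
        out["fdr"] = bh_fdr(out["p"].to_numpy())
        out["significant"] = (out["fdr"] < cfg.kegg_fdr) & (
            out["overlap"] >= cfg.go_min_overlap
        )
    return out.sort_values("p").set_index("term")
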