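"""Sub-cell-type discovery within one cell type using DD genes.

The imputed (un-normalized) matrix is subset to the DD genes, re-normalized
de novo, HVGs are selected with the standard thresholds, cells are embedded
on the principal components explaining > 2% variance each, and communities
are found on a shared-nearest-neighbour graph by Louvain modularity
optimization at resolution 0.3.  Cluster markers come from Wilcoxon
rank-sum tests with a 25% detection filter, and the per-cluster sex
composition flags sex-dominated clusters (> 90% one sex).
"""

from __future__ import annotations

import random as _random
import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .config import AnalysisConfig
from .datatypes import CountMatrix, NormalizedMatrix
from .preprocess import lognormalize, select_hvgs
from .stats import bh_fdr

__all__ = [
    "renormalize_dd",
    "choose_pcs",
    "SNNClusterer",
    "snn_cluster",
    "ClusterAssignment",
    "find_markers",
    "composition_summary",
]


def renormalize_dd(imputed: CountMatrix, dd_genes: list[str]) -> tuple[NormalizedMatrix, list[str]]:
    """Subset to DD genes, log-normalize de novo, and select HVGs."""
    if len(dd_genes) == 0:
        raise ValueError("empty DD gene list")
    sub = imputed.subset(genes=dd_genes)
    nm = lognormalize(sub)
    hvgs = select_hvgs(nm)
    return nm, hvgs


def choose_pcs(nm: NormalizedMatrix, var_frac: float = 0.02) -> tuple[int, np.ndarray]:
    """Number of leading PCs each explaining > ``var_frac`` of total variance.

    PCA is run on the centered (not scaled) cells x HVG matrix; a floor of
    2 PCs is enforced for degenerate inputs.  Returns (n_pcs, coords).
    """
    X = nm.values.T  # cells x genes
    if X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need >= 2 genes and >= 3 cells")
    n_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp).fit(X)
    shares = pca.explained_variance_ratio_
    n_pcs = int((shares > var_frac).sum())
    n_pcs = max(n_pcs, 2)
    coords = pca.transform(X)[:, :n_pcs]
    return n_pcs, coords


@dataclass
class ClusterAssignment:
    labels: pd.Series  # cell_id -> 0-based contiguous cluster label
    n_pcs: int
    resolution: float
    sex_counts: pd.DataFrame


class SNNClusterer(BaseEstimator, ClusterMixin):
    """Shared-nearest-neighbour Louvain clustering (sklearn clusterer).

    A kNN graph is built in PC space, edges are weighted by the Jaccard
    overlap of the two cells' neighbour sets, and Louvain modularity
    optimization (RB-configuration null model) at the given resolution
    yields the communities.  Labels are relabelled by decreasing cluster
    size so they are contiguous from 0 and deterministic given the seed.
    """

    def __init__(self, resolution: float = 0.3, k: int = 20, random_state: int = 0):
        self.resolution = resolution
        self.k = k
        self.random_state = random_state

    def fit_predict(self, X, y=None):
        X = np.asarray(X, dtype=float)  # cells x dims
        n = X.shape[0]
        k = min(self.k, n - 1)
        if k < 1:
            raise ValueError("need at least 2 cells")
        if k < self.k:
            warnings.warn(f"k reduced to {k}", stacklevel=2)
        if np.allclose(X, X[0]):
            self.labels_ = np.zeros(n, dtype=int)
            return self.labels_
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
        _, idx = nn.kneighbors(X)
        neigh = [set(r) for r in idx]  # includes self, matching Seurat's SNN
        edges, weights = [], []
        for i in range(n):
            for j in idx[i]:
                j = int(j)
                if j <= i:
                    continue
                inter = len(neigh[i] & neigh[j])
                union = len(neigh[i] | neigh[j])
                w = inter / union
                if w > 1.0 / 15.0:  # prune weak SNN edges
                    edges.append((i, j))
                    weights.append(w)
        g = ig.Graph(n=n, edges=edges)
        _random.seed(self.random_state)
        ig.set_random_number_generator(_random)
        part = g.community_multilevel(weights=weights, resolution=self.resolution)
        raw = np.array(part.membership)
        order = np.argsort(-np.bincount(raw), kind="stable")
        remap = np.empty_like(order)
        remap[order] = np.arange(order.size)
        self.labels_ = remap[raw]
        return self.labels_


def snn_cluster(
    nm: NormalizedMatrix,
    coords: np.ndarray,
    n_pcs: int,
    resolution: float = 0.3,
    k: int = 20,
    seed: int = 0,
) -> ClusterAssignment:
    labels = SNNClusterer(resolution=resolution, k=k, random_state=seed).fit_predict(coords)
    series = pd.Series(labels, index=nm.cell_ids, name="cluster")
    sex_counts = (
        pd.DataFrame({"cluster": labels, "sex": nm.sex})
        .value_counts()
        .unstack(fill_value=0)
    )
    return ClusterAssignment(
        labels=series, n_pcs=n_pcs, resolution=resolution, sex_counts=sex_counts
    )


def find_markers(
    nm: NormalizedMatrix,
    labels: pd.Series,
    cluster,
    other=None,
    min_pct: float = 0.25,
) -> pd.DataFrame:
    """Wilcoxon rank-sum markers of ``cluster`` vs ``other`` (default: rest).

    Genes expressed (> 0) in >= ``min_pct`` of either population are
    tested; p-values are BH-adjusted across tested genes and the effect is
    the difference of mean log expression (cluster minus comparison).
    """
    lab = labels.reindex(nm.cell_ids).to_numpy()
    in_mask = lab == cluster
    out_mask = (lab == other) if other is not None else ~in_mask
    if in_mask.sum() < 3 or out_mask.sum() < 3:
        raise ValueError("each compared group needs >= 3 cells")
    Xin = nm.values[:, in_mask]
    Xout = nm.values[:, out_mask]
    pct_in = (Xin > 0).mean(axis=1)
    pct_out = (Xout > 0).mean(axis=1)
    testable = (pct_in >= min_pct) | (pct_out >= min_pct)
    rows = []
    for g in np.flatnonzero(testable):
        try:
            _, p = sps.mannwhitneyu(Xin[g], Xout[g], alternative="two-sided")
        except ValueError:  # identical constant values
            p = 1.0
        rows.append(
            {
                "gene_id": nm.gene_ids[g],
                "cluster": cluster,
                "effect": float(Xin[g].mean() - Xout[g].mean()),
                "pct_in": float(pct_in[g]),
                "pct_out": float(pct_out[g]),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_fdr(out["p"].to_numpy())
        # effect size breaks ties among p-values at the test's resolution
        out["_abs_effect"] = out["effect"].abs()
        out = (
            out.sort_values(["fdr", "p", "_abs_effect"], ascending=[True, True, False])
            .drop(columns="_abs_effect")
            .set_index("gene_id")
        )
    return out


def composition_summary(labels: pd.Series, sex: np.ndarray,
                        dominated: float = 0.90) -> pd.DataFrame:
    """Per-cluster cell counts, sex counts and female percentage.

    Clusters with more than ``dominated`` of cells from one sex are flagged
    ``sex_dominated``; the rest are ``mixed``.
    """
    sex = np.asarray(sex)
    rows = []
    for c in sorted(labels.unique()):
        sel = labels.to_numpy() == c
        n = int(sel.sum())
        n_f = int((sex[sel] == "F").sum())
        n_m = n - n_f
        pct_f = 100.0 * n_f / n
        status = "sex_dominated" if max(pct_f, 100 - pct_f) > 100 * dominated else "mixed"
        rows.append({"cluster": c, "n": n, "n_F": n_f, "n_M": n_m,
                     "pct_F": pct_f, "status": status})
    return pd.DataFrame(rows).set_index("cluster")
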