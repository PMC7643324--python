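"""Per-cell gene-set scoring and differential-pathway tests.

:class:`GSVAScorer` produces a gene-set x cell matrix of enrichment scores
from a Kolmogorov-Smirnov-like weighted random walk: each gene's expression
is transformed to a Gaussian-kernel CDF across cells, genes are ranked per
cell, and each set's score is the signed maximum deviation difference of a
walk that steps up by the symmetric rank statistic on set genes and down
uniformly on the rest.  Positive scores mean the set's genes sit towards
the top of that cell's ranking.

:func:`diff_pathways` compares set scores between sexes with Welch's t
(FDR < 5e-5 and |mean difference| > 0.1 by default), and
:func:`percell_gsea_nes` computes per-cell GSEA normalized enrichment
scores for a single set (used for the housekeeping / cell-cycle sanity
check on sub-cell types).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .config import AnalysisConfig
from .datatypes import GeneSetCollection, NormalizedMatrix
from .stats import bh_fdr, ks_test, welch_t

__all__ = ["GSVAScorer", "gsva_scores", "diff_pathways", "percell_gsea_nes"]


def _kernel_cdf(X: np.ndarray) -> np.ndarray:
    """Per-gene Gaussian-kernel CDF of each value across cells.

    Bandwidth = sample sd * n^(-1/5); constant genes map to 0.5 everywhere.
    """
    n_genes, n_cells = X.shape
    Z = np.empty_like(X, dtype=float)
    h = X.std(axis=1, ddof=1) * n_cells ** (-1.0 / 5.0)
    for g in range(n_genes):
        if h[g] <= 0 or not np.isfinite(h[g]):
            Z[g] = 0.5
            continue
        Z[g] = sps.norm.cdf((X[g][:, None] - X[g][None, :]) / h[g]).mean(axis=1)
    return Z


def _walk_es(weights: np.ndarray, indicator: np.ndarray) -> float:
    """Signed maximum-deviation-difference ES of one weighted KS walk.

    ``weights`` and ``indicator`` are aligned to the walk order (best rank
    first).  A set spanning every gene carries no discrimination and scores
    0 by convention.
    """
    k = int(indicator.sum())
    p = indicator.size
    if k == 0 or k == p:
        return 0.0
    w = weights * indicator
    tot = w.sum()
    inc = np.cumsum(w) / (tot if tot > 0 else 1.0)
    dec = np.cumsum(1.0 - indicator) / (p - k)
    nu = inc - dec
    return float(max(nu.max(), 0.0) + min(nu.min(), 0.0))


class GSVAScorer(BaseEstimator, TransformerMixin):
    """Gene-set variation scores per cell (sklearn transformer).

    ``fit`` stores the gene universe and the sets intersected with it
    (sets with fewer than ``min_size`` present genes are excluded and
    listed in ``excluded_sets_``); ``transform`` maps a gene x cell matrix
    to a set x cell score matrix with entries in [-1, 1].
    """

    def __init__(self, gene_sets: GeneSetCollection | dict, min_size: int = 5,
                 tau: float = 1.0):
        self.gene_sets = gene_sets
        self.min_size = min_size
        self.tau = tau

    def fit(self, X, y=None, *, gene_ids):
        gene_ids = list(gene_ids)
        sets = (
            self.gene_sets.sets
            if isinstance(self.gene_sets, GeneSetCollection)
            else dict(self.gene_sets)
        )
        pos = {g: i for i, g in enumerate(gene_ids)}
        self.set_indices_ = {}
        self.excluded_sets_ = []
        for name, genes in sets.items():
            idx = [pos[g] for g in genes if g in pos]
            if len(idx) >= self.min_size:
                self.set_indices_[name] = np.array(idx)
            else:
                self.excluded_sets_.append(name)
        self.gene_ids_ = gene_ids
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] < 2:
            raise ValueError("need >= 2 cells")
        p, n_cells = X.shape
        Z = _kernel_cdf(X)
        names = list(self.set_indices_)
        scores = np.zeros((len(names), n_cells))
        members = np.zeros((len(names), p), dtype=bool)
        for s, name in enumerate(names):
            members[s, self.set_indices_[name]] = True
        for j in range(n_cells):
            order = np.argsort(-Z[:, j], kind="stable")
            ranks = np.empty(p)
            ranks[order] = np.arange(1, p + 1)
            stat = np.abs(p / 2.0 - ranks) ** self.tau  # symmetric rank statistic
            w_ord = stat[order]
            for s in range(len(names)):
                scores[s, j] = _walk_es(w_ord, members[s, order].astype(float))
        self.set_names_ = names
        return scores


def gsva_scores(
    nm: NormalizedMatrix, gsc: GeneSetCollection, min_size: int = 5
) -> pd.DataFrame:
    """Set x cell GSVA-style scores as a DataFrame (sets in rows)."""
    scorer = GSVAScorer(gsc, min_size=min_size).fit(nm.values, gene_ids=nm.gene_ids)
    scores = scorer.transform(nm.values)
    return pd.DataFrame(scores, index=scorer.set_names_, columns=nm.cell_ids)


def diff_pathways(sm: pd.DataFrame, sex: np.ndarray,
                  cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Welch's t per set between sexes, BH across sets.

    Significant iff FDR < ``gsva_fdr`` and |mean_F - mean_M| > ``gsva_diff``.
    """
    cfg = cfg or AnalysisConfig()
    sex = np.asarray(sex)
    f = sex == "F"
    m = sex == "M"
    if f.sum() < 2 or m.sum() < 2:
        raise ValueError("need >= 2 cells of each sex")
    columns = ["set", "mean_F", "mean_M", "t", "p", "fdr", "significant"]
    if len(sm) == 0:
        return pd.DataFrame(columns=columns).set_index("set")
    rows = []
    for name in sm.index:
        x = sm.loc[name].to_numpy()[f]
        y = sm.loc[name].to_numpy()[m]
        t, p = welch_t(x, y)
        rows.append({"set": name, "mean_F": x.mean(), "mean_M": y.mean(),
                     "t": t, "p": p})
    out = pd.DataFrame(rows).set_index("set")
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = (out["fdr"] < cfg.gsva_fdr) & (
        (out["mean_F"] - out["mean_M"]).abs() > cfg.gsva_diff
    )
    return out


def percell_gsea_nes(
    nm: NormalizedMatrix,
    gene_set,
    sex: np.ndarray | None = None,
    n_perm: int = 200,
    seed: int = 0,
) -> tuple[pd.Series, dict]:
    """Per-cell GSEA normalized enrichment score for one gene set.

    Per cell, genes are ranked by normalized expression (weight =
    expression, exponent 1) and the weighted KS walk gives an ES; the NES
    divides the ES by the mean |ES| of gene-label permutations with the
    same sign.  Returns the per-cell NES and a between-sex comparison
    (Welch and KS p-values).
    """
    rng = np.random.default_rng(seed)
    sex = np.asarray(sex if sex is not None else nm.sex)
    gene_ids = list(nm.gene_ids)
    pos = {g: i for i, g in enumerate(gene_ids)}
    idx = [pos[g] for g in gene_set if g in pos]
    if len(idx) < 5:
        raise ValueError("gene set shares fewer than 5 genes with the matrix")
    p, n_cells = nm.values.shape
    member = np.zeros(p, dtype=bool)
    member[idx] = True
    k = member.sum()

    nes = np.empty(n_cells)
    for j in range(n_cells):
        # an independent permutation panel per cell: a shared panel would
        # couple its random gene overlap to every cell's ranking the same
        # way and bias between-group NES comparisons
        perm_members = np.zeros((p, n_perm), dtype=bool)
        cols = np.argsort(rng.random((n_perm, p)), axis=1)[:, :k]
        for b in range(n_perm):
            perm_members[cols[b], b] = True
        order = np.argsort(-nm.values[:, j], kind="stable")
        w = np.abs(nm.values[order, j])
        es = _walk_es(w, member[order].astype(float))
        P = perm_members[order]
        wtot = (w[:, None] * P).sum(axis=0)
        wtot[wtot == 0] = 1.0
        inc = np.cumsum(w[:, None] * P, axis=0) / wtot
        dec = np.cumsum(~P, axis=0) / (p - k)
        nu = inc - dec
        es_perm = np.maximum(nu.max(axis=0), 0.0) + np.minimum(nu.min(axis=0), 0.0)
        same_sign = es_perm[np.sign(es_perm) == np.sign(es)] if es != 0 else es_perm
        denom = np.abs(same_sign).mean() if same_sign.size else np.abs(es_perm).mean()
        nes[j] = es / denom if denom > 0 else 0.0

    series = pd.Series(nes, index=nm.cell_ids, name="NES")
    f = nes[sex == "F"]
    m = nes[sex == "M"]
    comparison = {}
    if f.size >= 2 and m.size >= 2:
        _, comparison["welch_p"] = welch_t(f, m)
        _, comparison["ks_p"] = ks_test(f, m)
    return series, comparison
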