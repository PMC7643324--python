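"""QC, dropout imputation, normalization, batch correction and cell/gene
selection.

The imputation stage follows the gamma-normal mixture approach: cells are
spectrally clustered into subpopulations, each gene's scaled log expression
in each subpopulation is modelled as ``lambda * Gamma + (1 - lambda) *
Normal`` (the gamma component absorbs dropout mass near zero), and entries
whose posterior dropout probability exceeds a threshold are re-estimated by
non-negative regression of the cell on its most similar neighbours using
only that cell's confidently observed genes.

Transformer-shaped stages (:class:`LogNormalizer`, :class:`DropoutImputer`,
:class:`MNNCorrector`, :class:`HVGSelector`) follow the scikit-learn
estimator protocol; module-level functions wrap them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import SpectralClustering
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .config import AnalysisConfig
from .datatypes import CountMatrix, NormalizedMatrix
from .stats import ks_test

__all__ = [
    "QCReport",
    "qc_filter",
    "lognormalize",
    "LogNormalizer",
    "DropoutImputer",
    "impute_dropouts",
    "ImputationModel",
    "nb_loglik_compare",
    "MNNCorrector",
    "mnn_correct",
    "HVGSelector",
    "select_hvgs",
    "embedding_consistency_filter",
    "library_balance_check",
]


# --- QC -----------------------------------------------------------------


@dataclass
class QCReport:
    cells_removed: pd.DataFrame  # index cell_id, column reason
    genes_removed: pd.DataFrame  # index gene_id, column reason
    detected_genes: pd.Series  # per input cell
    post_rrna_totals: pd.Series  # per input cell


def qc_filter(cm: CountMatrix, cfg: AnalysisConfig | None = None) -> tuple[CountMatrix, QCReport]:
    """Remove low-quality cells, then undetected and chrY genes.

    Cells are kept iff they detect >= ``min_genes_per_cell`` genes (count >=
    1) and carry >= ``min_counts_per_cell`` total reads after subtracting the
    45S pre-rRNA gene (Rn45s), both bounds inclusive.  Genes are then kept
    iff they reach count >= ``gene_detect_count`` in >= ``gene_detect_cells``
    retained cells and do not lie on chromosome Y; the uniformly overabundant
    rRNA gene itself is also dropped.
    """
    cfg = cfg or AnalysisConfig()
    counts = cm.counts
    detected = (counts >= 1).sum(axis=0)
    totals = counts.sum(axis=0)
    rrna_mask = cm.var.index == cfg.rrna_gene
    if rrna_mask.any():
        totals = totals - counts[rrna_mask].sum(axis=0)
    keep_cells = (detected >= cfg.min_genes_per_cell) & (totals >= cfg.min_counts_per_cell)

    reasons = np.where(
        detected < cfg.min_genes_per_cell, "low_genes", "low_counts"
    )
    cells_removed = pd.DataFrame(
        {"reason": reasons[~keep_cells]}, index=cm.obs.index[~keep_cells]
    )

    sub = counts[:, keep_cells]
    detected_in = (sub >= cfg.gene_detect_count).sum(axis=1)
    keep_genes = (detected_in >= cfg.gene_detect_cells) & (
        cm.var["chrom"].to_numpy() != "Y"
    ) & ~rrna_mask
    gene_reason = np.where(
        cm.var["chrom"].to_numpy() == "Y", "chrY", "undetected"
    )
    genes_removed = pd.DataFrame(
        {"reason": gene_reason[~keep_genes]}, index=cm.var.index[~keep_genes]
    )

    if keep_cells.sum() == 0 or keep_genes.sum() == 0:
        raise ValueError("QC filtering removed every cell or gene")
    out = cm.subset(genes=keep_genes, cells=keep_cells)
    report = QCReport(
        cells_removed=cells_removed,
        genes_removed=genes_removed,
        detected_genes=pd.Series(detected, index=cm.obs.index),
        post_rrna_totals=pd.Series(totals, index=cm.obs.index),
    )
    return out, report


# --- log-normalization --------------------------------------------------


class LogNormalizer(BaseEstimator, TransformerMixin):
    """Per-cell library-size log-normalization: ln(count / total * scale + 1).

    Stateless transformer over gene x cell count arrays; kept as an
    estimator so it slots into sklearn pipelines.
    """

    def __init__(self, scale: float = 1e4):
        self.scale = scale

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if np.any(X.sum(axis=0) == 0):
            raise ValueError("all-zero cell cannot be normalized")
        self.n_features_in_ = X.shape[0]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        totals = X.sum(axis=0)
        if np.any(totals == 0):
            raise ValueError("all-zero cell cannot be normalized")
        return np.log1p(X / totals * self.scale)


def lognormalize(cm: CountMatrix, scale: float = 1e4) -> NormalizedMatrix:
    values = LogNormalizer(scale=scale).fit(cm.counts).transform(cm.counts)
    return NormalizedMatrix(values, cm.obs.copy(), cm.var.copy(), provenance=["lognorm"])


# --- gamma-normal mixture imputation ------------------------------------

_LOG_OFFSET = 1.01  # keeps scaled log values strictly positive for the gamma


@dataclass
class ImputationModel:
    subpopulation: np.ndarray  # per cell
    params: dict  # (gene_idx, subpop) -> dict(lam, shape, rate, mu, sd)
    dropout_prob: np.ndarray  # gene x cell d_gc
    flagged_genes: list = field(default_factory=list)


_GAMMA_MEAN_CAP = 1.0  # scaled-log units; the gamma models the detection floor


def _gamma_normal_em(v: np.ndarray, max_iter: int = 100, tol: float = 1e-4) -> dict:
    """EM fit of lam*Gamma(shape, rate) + (1-lam)*Normal(mu, sd) on v > 0.

    The gamma component models dropout mass near the detection floor; its
    mean is capped at ``_GAMMA_MEAN_CAP`` so it cannot annex the lower half
    of a genuinely unimodal expression distribution.  Gamma parameters are
    updated by weighted moment matching (stable and adequate for posterior
    dropout probabilities); degenerate fits fall back to lam = 0.
    """
    v = np.asarray(v, dtype=float)
    if v.size < 5 or np.var(v) < 1e-8:
        return {"lam": 0.0, "shape": 1.0, "rate": 1.0, "mu": float(np.mean(v)),
                "sd": max(float(np.std(v)), 1e-3), "converged": False}
    med = np.median(v)
    low, high = v[v <= med], v[v > med]
    lam = 0.5
    m_lo = min(max(float(np.mean(low)), 1e-3), _GAMMA_MEAN_CAP)
    v_lo = max(float(np.var(low)), 1e-6)
    shape, rate = m_lo**2 / v_lo, m_lo / v_lo
    mu, sd = float(np.mean(high)), max(float(np.std(high)), 1e-3)
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        with np.errstate(over="ignore", under="ignore"):
            lg = sps.gamma.logpdf(v, a=shape, scale=1.0 / rate)
            ln = sps.norm.logpdf(v, loc=mu, scale=sd)
        lg = np.where(np.isfinite(lg), lg, -1e10)
        num = np.log(max(lam, 1e-12)) + lg
        den = np.logaddexp(num, np.log(max(1 - lam, 1e-12)) + ln)
        w = np.exp(num - den)  # posterior of gamma component
        lam = float(np.mean(w))
        if lam < 1e-4 or lam > 1 - 1e-4:
            lam = float(np.clip(lam, 0.0, 1.0))
            break
        sw = w.sum()
        m_g = min(float((w * v).sum() / sw), _GAMMA_MEAN_CAP)
        var_g = max(float((w * (v - m_g) ** 2).sum() / sw), 1e-6)
        shape, rate = max(m_g**2 / var_g, 1e-3), max(m_g / var_g, 1e-6)
        swn = (1 - w).sum()
        mu = float(((1 - w) * v).sum() / swn)
        sd = max(float(np.sqrt(((1 - w) * (v - mu) ** 2).sum() / swn)), 1e-3)
        ll = float(den.sum())
        if abs(ll - prev) < tol:
            converged = True
            break
        prev = ll
    return {"lam": lam, "shape": shape, "rate": rate, "mu": mu, "sd": sd,
            "converged": converged}


def _dropout_posterior(v: np.ndarray, fit: dict) -> np.ndarray:
    lam = fit["lam"]
    if lam <= 0:
        return np.zeros_like(v)
    with np.errstate(over="ignore", under="ignore"):
        lg = sps.gamma.logpdf(v, a=fit["shape"], scale=1.0 / fit["rate"])
        ln = sps.norm.logpdf(v, loc=fit["mu"], scale=fit["sd"])
    lg = np.where(np.isfinite(lg), lg, -1e10)
    num = np.log(max(lam, 1e-12)) + lg
    den = np.logaddexp(num, np.log(max(1 - lam, 1e-12)) + ln)
    return np.exp(num - den)


class DropoutImputer(BaseEstimator, TransformerMixin):
    """scImpute-style dropout imputation (sklearn transformer over counts).

    Parameters
    ----------
    n_subpops : number of cell subpopulations for spectral clustering.
    threshold : posterior dropout probability above which an entry is
        re-estimated (0.5 by default).
    n_neighbors : number of most-similar same-subpopulation cells used in
        the non-negative regression.
    """

    def __init__(self, n_subpops: int = 1, threshold: float = 0.5,
                 n_neighbors: int = 10, n_pcs: int = 20, random_state: int = 0):
        self.n_subpops = n_subpops
        self.threshold = threshold
        self.n_neighbors = n_neighbors
        self.n_pcs = n_pcs
        self.random_state = random_state

    def fit(self, X, y=None):
        """Cluster cells, fit per-gene mixtures, compute dropout posteriors."""
        X = np.asarray(X, dtype=float)  # genes x cells
        n_genes, n_cells = X.shape
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        totals = X.sum(axis=0)
        if np.any(totals == 0):
            raise ValueError("all-zero cell")
        V = np.log(X / totals * 1e4 + _LOG_OFFSET)  # scaled log expression

        if self.n_subpops == 1 or n_cells <= 3 * self.n_subpops:
            labels = np.zeros(n_cells, dtype=int)
        else:
            n_pcs = min(self.n_pcs, n_cells - 1, n_genes)
            pcs = PCA(n_components=n_pcs, random_state=self.random_state).fit_transform(V.T)
            d = np.linalg.norm(pcs[:, None, :] - pcs[None, :, :], axis=-1)
            sigma = np.median(d[np.triu_indices(n_cells, 1)])
            aff = np.exp(-(d**2) / (2 * max(sigma, 1e-8) ** 2))
            labels = SpectralClustering(
                n_clusters=self.n_subpops, affinity="precomputed",
                random_state=self.random_state, assign_labels="discretize",
            ).fit_predict(aff)
        counts_per = np.bincount(labels, minlength=self.n_subpops)
        if np.any(counts_per[: self.n_subpops] < 3):
            raise ValueError("a subpopulation has fewer than 3 cells")

        d_gc = np.zeros_like(V)
        params: dict = {}
        flagged: list = []
        for s in range(int(labels.max()) + 1):
            cells = np.flatnonzero(labels == s)
            for g in range(n_genes):
                fit = _gamma_normal_em(V[g, cells])
                if not fit["converged"] and fit["lam"] > 0:
                    flagged.append((g, s))
                params[(g, s)] = fit
                d_gc[g, cells] = _dropout_posterior(V[g, cells], fit)

        self.model_ = ImputationModel(
            subpopulation=labels, params=params, dropout_prob=d_gc,
            flagged_genes=flagged,
        )
        self._V = V
        self._totals = totals
        return self

    def transform(self, X):
        """Re-estimate high-dropout entries cell by cell; return counts scale."""
        X = np.asarray(X, dtype=float)
        V = self._V
        d_gc = self.model_.dropout_prob
        labels = self.model_.subpopulation
        out = X.copy()
        n_genes, n_cells = X.shape
        for c in range(n_cells):
            to_impute = np.flatnonzero(d_gc[:, c] > self.threshold)
            if to_impute.size == 0:
                continue
            confident = np.flatnonzero(d_gc[:, c] <= self.threshold)
            peers = np.flatnonzero((labels == labels[c]) & (np.arange(n_cells) != c))
            if peers.size == 0 or confident.size == 0:
                continue
            dist = np.linalg.norm(
                V[np.ix_(confident, peers)] - V[confident, c][:, None], axis=0
            )
            nbr = peers[np.argsort(dist)[: self.n_neighbors]]
            A = V[np.ix_(confident, nbr)]
            beta, _ = optimize.nnls(A, V[confident, c])
            pred = V[np.ix_(to_impute, nbr)] @ beta
            new_counts = np.maximum(
                (np.exp(pred) - _LOG_OFFSET) / 1e4 * self._totals[c], 0.0
            )
            out[to_impute, c] = new_counts
        return out


def impute_dropouts(
    cm: CountMatrix, n_subpops: int = 1, threshold: float = 0.5, seed: int = 0
) -> tuple[CountMatrix, ImputationModel]:
    imp = DropoutImputer(n_subpops=n_subpops, threshold=threshold, random_state=seed)
    imputed = imp.fit(cm.counts).transform(cm.counts)
    out = CountMatrix(imputed, cm.obs.copy(), cm.var.copy())
    return out, imp.model_


# --- NB likelihood comparison -------------------------------------------


def _nb_loglik(x: np.ndarray, mu: float, theta: float) -> float:
    p = theta / (theta + mu)
    return float(sps.nbinom.logpmf(np.round(x).astype(int), theta, p).sum())


def fit_nb(x: np.ndarray) -> tuple[float, float, float]:
    """MLE negative-binomial fit (mean, dispersion theta, loglik).

    The mean MLE is the sample mean; the dispersion maximizes the profile
    log-likelihood by bounded search over log theta.
    """
    x = np.round(np.asarray(x, dtype=float))
    mu = float(np.mean(x))
    if mu <= 0:
        raise ValueError("all-zero gene: NB likelihood undefined")

    def neg(logt):
        return -_nb_loglik(x, mu, float(np.exp(logt)))

    res = optimize.minimize_scalar(neg, bounds=(np.log(1e-3), np.log(1e6)), method="bounded")
    theta = float(np.exp(res.x))
    return mu, theta, -float(res.fun)


def nb_loglik_compare(raw: CountMatrix, imputed: CountMatrix) -> pd.DataFrame:
    """Per gene, max-likelihood NB fits to raw and imputed counts.

    Returns a DataFrame with columns loglik_raw / loglik_imputed; all-zero
    genes are flagged and excluded (NaN log-likelihoods).
    """
    if raw.counts.shape != imputed.counts.shape:
        raise ValueError("matrices must share gene/cell sets")
    rows = []
    for g in range(raw.n_genes):
        row = {"gene_id": raw.gene_ids[g]}
        for label, mat in (("raw", raw.counts), ("imputed", imputed.counts)):
            x = mat[g]
            if np.all(x == 0):
                row[f"loglik_{label}"] = np.nan
                row["flagged"] = True
            else:
                row[f"loglik_{label}"] = fit_nb(x)[2]
                row.setdefault("flagged", False)
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


# --- MNN batch correction -----------------------------------------------


class MNNCorrector(BaseEstimator, TransformerMixin):
    """Sequential pairwise mutual-nearest-neighbour batch correction.

    Cells are cosine-normalized; mutual k-NN pairs between the reference
    (first batch, growing as batches merge) and each incoming batch define
    per-pair difference vectors, and each incoming cell is shifted by a
    Gaussian-kernel-weighted average of those vectors.  Corrected values are
    returned on the log scale.
    """

    def __init__(self, k: int = 20, sigma: float | None = None):
        self.k = k
        self.sigma = sigma

    def fit(self, X, y=None):
        return self

    def fit_transform(self, X, y=None, *, batches=None):
        return self.transform(X, batches=batches)

    def transform(self, X, *, batches):
        X = np.asarray(X, dtype=float)  # genes x cells
        batches = np.asarray(batches)
        uniq = pd.unique(batches)
        if len(uniq) < 2:
            return X.copy()
        out = X.copy()
        ref_cells = np.flatnonzero(batches == uniq[0])
        for b in uniq[1:]:
            new_cells = np.flatnonzero(batches == b)
            out = self._correct_pair(out, ref_cells, new_cells)
            ref_cells = np.concatenate([ref_cells, new_cells])
        return out

    def _correct_pair(self, X, ref_cells, new_cells):
        def unit(M):
            n = np.linalg.norm(M, axis=0, keepdims=True)
            return M / np.where(n == 0, 1.0, n)

        ref = unit(X[:, ref_cells])
        new = unit(X[:, new_cells])
        k = min(self.k, len(ref_cells), len(new_cells))
        if k < self.k:
            warnings.warn(f"MNN k reduced to {k}", stacklevel=2)
        nn_rn = NearestNeighbors(n_neighbors=k).fit(ref.T)
        _, idx_new_to_ref = nn_rn.kneighbors(new.T)
        nn_nr = NearestNeighbors(n_neighbors=k).fit(new.T)
        _, idx_ref_to_new = nn_nr.kneighbors(ref.T)
        new_sets = [set(r) for r in idx_new_to_ref]
        pairs = [
            (r, n)
            for r in range(len(ref_cells))
            for n in idx_ref_to_new[r]
            if r in new_sets[n]
        ]
        if not pairs:
            raise ValueError("no mutual nearest neighbours between batches")
        pr = np.array([p[0] for p in pairs])
        pn = np.array([p[1] for p in pairs])
        diffs = X[:, ref_cells[pr]] - X[:, new_cells[pn]]  # log scale
        # kernel weights on cosine-space distance to paired new-batch cells
        d = np.linalg.norm(new[:, :, None] - new[:, pn][:, None, :], axis=0)
        sigma = self.sigma or max(float(np.median(d)), 1e-8)
        w = np.exp(-(d**2) / (2 * sigma**2))
        w /= w.sum(axis=1, keepdims=True)
        corr = diffs @ w.T  # genes x new cells
        X = X.copy()
        X[:, new_cells] += corr
        return X


def mnn_correct(nm: NormalizedMatrix, k: int = 20) -> NormalizedMatrix:
    values = MNNCorrector(k=k).transform(nm.values, batches=nm.obs["batch"].to_numpy())
    return NormalizedMatrix(
        values, nm.obs.copy(), nm.var.copy(), provenance=[*nm.provenance, "mnn"]
    )


# --- HVG selection ------------------------------------------------------


class HVGSelector(BaseEstimator):
    """Highly variable genes by binned standardized log dispersion.

    Per gene, the mean normalized expression and ``log(var / mean)`` are
    computed; log dispersions are z-standardized within equal-frequency
    mean bins, and genes pass with standardized dispersion > ``disp_cutoff``
    and mean strictly inside (``mean_lo``, ``mean_hi``).
    """

    def __init__(self, disp_cutoff: float = 0.5, mean_lo: float = 0.0125,
                 mean_hi: float = 3.0, n_bins: int = 20):
        self.disp_cutoff = disp_cutoff
        self.mean_lo = mean_lo
        self.mean_hi = mean_hi
        self.n_bins = n_bins

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)  # genes x cells
        if X.shape[1] < 2:
            raise ValueError("need >= 2 cells")
        mean = X.mean(axis=1)
        var = X.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            disp = np.where(mean > 0, var / mean, 0.0)
            log_disp = np.where(disp > 0, np.log(disp), -np.inf)
        n_bins = min(self.n_bins, max(X.shape[0] // 2, 1))
        order = np.argsort(mean, kind="stable")
        bins = np.empty(X.shape[0], dtype=int)
        bins[order] = np.minimum(
            (np.arange(X.shape[0]) * n_bins) // X.shape[0], n_bins - 1
        )
        z = np.full(X.shape[0], -np.inf)
        for b in range(n_bins):
            sel = (bins == b) & np.isfinite(log_disp)
            if sel.sum() == 0:
                continue
            mu_b = log_disp[sel].mean()
            sd_b = log_disp[sel].std()
            z[sel] = (log_disp[sel] - mu_b) / (sd_b if sd_b > 0 else 1.0)
        self.mean_ = mean
        self.dispersion_z_ = z
        self.support_ = (
            (z > self.disp_cutoff) & (mean > self.mean_lo) & (mean < self.mean_hi)
        )
        return self

    def get_support(self):
        return self.support_


def select_hvgs(nm: NormalizedMatrix, disp_cutoff: float = 0.5,
                mean_lo: float = 0.0125, mean_hi: float = 3.0,
                n_bins: int = 20) -> list[str]:
    sel = HVGSelector(disp_cutoff, mean_lo, mean_hi, n_bins).fit(nm.values)
    return list(nm.gene_ids[sel.get_support()])


# --- embedding consistency ----------------------------------------------


def embedding_consistency_filter(
    nm: NormalizedMatrix,
    cell_type: np.ndarray | None = None,
    n_pcs: int = 50,
    perplexity: float = 30.0,
    reps: int = 5,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Remove cells recurrently grouped away from their annotated type.

    For each of ``reps`` 2-D t-SNE embeddings (distinct random seeds) the
    label of every cell's nearest neighbour is recorded; cells whose
    neighbour disagrees with their own label in a majority of repetitions
    are removed.  With a single cell type no cell can be removed.
    """
    labels = np.asarray(cell_type if cell_type is not None else nm.obs["cell_type"])
    cells = list(nm.cell_ids)
    if len(set(labels)) < 2:
        return cells, []
    X = nm.values.T  # cells x genes
    n = X.shape[0]
    n_pcs = min(n_pcs, n - 1, X.shape[1])
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)
    perp = perplexity
    if perp >= (n - 1) / 3:
        perp = max((n - 1) / 3 - 1, 2.0)
        warnings.warn(f"perplexity reduced to {perp:.1f}", stacklevel=2)
    inconsistent = np.zeros(n, dtype=int)
    for r in range(reps):
        emb = TSNE(
            n_components=2, perplexity=perp, random_state=seed + r, init="pca"
        ).fit_transform(pcs)
        nn = NearestNeighbors(n_neighbors=2).fit(emb)
        _, idx = nn.kneighbors(emb)
        neighbor = idx[:, 1]
        inconsistent += (labels[neighbor] != labels).astype(int)
    removed_mask = inconsistent > reps / 2
    kept = [c for c, r in zip(cells, removed_mask) if not r]
    removed = [c for c, r in zip(cells, removed_mask) if r]
    return kept, removed


# --- library-size balance -----------------------------------------------


def library_balance_check(cm: CountMatrix) -> pd.DataFrame:
    """Two-sample KS on per-cell library sizes between sexes per cell type."""
    totals = cm.counts.sum(axis=0)
    rows = []
    for ct in pd.unique(cm.cell_type):
        sel = cm.cell_type == ct
        f = totals[sel & (cm.sex == "F")]
        m = totals[sel & (cm.sex == "M")]
        if f.size == 0 or m.size == 0:
            rows.append({"cell_type": ct, "D": np.nan, "p": np.nan, "skipped": True})
            continue
        D, p = ks_test(f, m)
        rows.append({"cell_type": ct, "D": D, "p": p, "skipped": False})
    return pd.DataFrame(rows).set_index("cell_type")
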