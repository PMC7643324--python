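"""Promoter scanning, PANDA network inference and differential targeting.

The chain: promoter windows around annotated TSSs -> log-odds PWM scanning
with exact score-to-p mapping under the background model -> binary TF x
gene motif prior -> PANDA message passing integrating the prior with TF-TF
interactions and gene coexpression -> jackknife ensembles of small-subset
networks per sex -> Welch tests of edge Z-scores and of out-/in-degree
(active-edge weight sums) between the ensembles.

PANDA normalizes every input so each entry is the average of its row- and
column-z-scores scaled by 1/sqrt(2), then iterates responsibility
``R = T(P, W)`` and availability ``A = T(W, C)`` updates, where ``T`` is
the continuous Tanimoto similarity
``T(x, y) = <x, y> / sqrt(|x|^2 + |y|^2 - |<x, y>|)``, nudging the edge
matrix ``W <- (1 - alpha) W + alpha (R + A) / 2`` and refreshing the PPI
and coexpression matrices from ``W`` with diagonal damping until the mean
update magnitude drops below tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .config import AnalysisConfig
from .datatypes import PWM, NormalizedMatrix, PPIMatrix, TSSRecord
from .stats import bh_fdr

__all__ = [
    "PromoterSet",
    "define_promoters",
    "scan_pwm",
    "PWMHit",
    "build_motif_prior",
    "coexpression",
    "PandaInference",
    "PandaNetwork",
    "panda_infer",
    "NetworkEnsemble",
    "jackknife_ensembles",
    "differential_edges",
    "differential_degrees",
]


# --- promoters ----------------------------------------------------------


@dataclass
class PromoterSet:
    """Per-gene promoter windows (1-based inclusive coordinates)."""

    windows: dict  # gene_id -> dict(chrom, start, end, strand, n_tss)
    dropped_genes: list = field(default_factory=list)  # > 2 TSSs
    clipped_genes: list = field(default_factory=list)


def define_promoters(
    tss: list[TSSRecord],
    single: tuple[int, int] = (-750, 250),
    double: tuple[int, int] = (-1000, 500),
) -> PromoterSet:
    """Promoter windows around the TSS (1 TSS) or TSS midpoint (2 TSSs).

    Plus-strand windows run from ``anchor + upstream`` to ``anchor +
    downstream``; minus-strand windows mirror the extents.  Genes with more
    than two distinct TSS positions are dropped; windows extending below
    position 1 are clipped and flagged.
    """
    by_gene: dict[str, list[TSSRecord]] = {}
    for r in tss:
        by_gene.setdefault(r.gene_id, []).append(r)
    windows: dict = {}
    dropped, clipped = [], []
    for gene, recs in by_gene.items():
        positions = sorted(set(r.pos for r in recs))
        if len(positions) > 2:
            dropped.append(gene)
            continue
        strand = recs[0].strand
        chrom = recs[0].chrom
        if len(positions) == 1:
            anchor = positions[0]
            up, down = single
        else:
            anchor = (positions[0] + positions[1]) // 2
            up, down = double
        if strand == "+":
            start, end = anchor + up, anchor + down
        else:
            start, end = anchor - down, anchor - up
        if start < 1:
            start = 1
            clipped.append(gene)
        windows[gene] = {
            "chrom": chrom, "start": start, "end": end,
            "strand": strand, "n_tss": len(positions),
        }
    return PromoterSet(windows=windows, dropped_genes=dropped, clipped_genes=clipped)


# --- PWM scanning -------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class PWMHit:
    position: int  # 0-based offset on the forward sequence
    strand: str
    score: float
    p: float


def _log_odds(pwm: PWM, background: np.ndarray, pseudocount: float) -> np.ndarray:
    padj = (pwm.matrix + pseudocount * background[:, None]) / (1.0 + pseudocount)
    return np.log2(padj / background[:, None])


def _score_distribution(lo: np.ndarray, background: np.ndarray,
                        max_exact_states: int = 4**12) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of window scores under the background model.

    Partial sums accumulate left to right, matching the scanner exactly, so
    for short motifs the p-values coincide bit-for-bit with brute-force
    enumeration.  Very long motifs fall back to rounding partial sums to
    1e-6 (merging numerically indistinguishable states).
    """
    L = lo.shape[1]
    round_keys = 4**L > max_exact_states
    dist: dict[float, float] = {0.0: 1.0}
    for j in range(L):
        new: dict[float, float] = {}
        for s, pr in dist.items():
            for b in range(4):
                key = s + lo[b, j]
                if round_keys:
                    key = round(key, 6)
                new[key] = new.get(key, 0.0) + pr * background[b]
        dist = new
    scores = np.array(sorted(dist))
    probs = np.array([dist[s] for s in scores])
    tail = np.cumsum(probs[::-1])[::-1]  # P(S >= score[i])
    return scores, tail


def scan_pwm(
    seq: str,
    pwm: PWM,
    p_thresh: float = 5e-5,
    background: np.ndarray | None = None,
    pseudocount: float = 0.1,
) -> list[PWMHit]:
    """Scan both strands of ``seq`` for ``pwm`` occurrences.

    Windows are scored by summed log2 odds versus the background; the
    score-to-p map is the exact distribution of window scores under the
    iid background model, and hits with ``p < p_thresh`` are returned.
    Windows containing N are skipped; characters outside {A, C, G, T, N}
    raise.
    """
    seq = seq.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence contains invalid characters")
    L = pwm.length
    if L > len(seq):
        raise ValueError("sequence shorter than motif")
    bg = np.asarray(background if background is not None else [0.25] * 4, dtype=float)
    lo = _log_odds(pwm, bg, pseudocount)
    scores_null, tail = _score_distribution(lo, bg)

    def window_score(s: str) -> float | None:
        total = 0.0
        for j, ch in enumerate(s):
            if ch == "N":
                return None
            total += lo[_BASE_INDEX[ch], j]
        return total

    hits: list[PWMHit] = []
    rc = seq.translate(_COMPLEMENT)[::-1]
    for strand, s in (("+", seq), ("-", rc)):
        for off in range(len(s) - L + 1):
            sc = window_score(s[off : off + L])
            if sc is None:
                continue
            i = np.searchsorted(scores_null, sc, side="left")
            p = float(tail[i]) if i < tail.size else 0.0
            if p < p_thresh:
                pos = off if strand == "+" else len(seq) - L - off
                hits.append(PWMHit(position=pos, strand=strand, score=float(sc), p=p))
    return hits


def build_motif_prior(
    hits: dict,
    tf_ids: list[str],
    promoters: PromoterSet,
    expressed_genes,
    gene_chrom: dict,
) -> pd.DataFrame:
    """Binary TF x gene prior from per-(TF, gene) hit lists.

    A gene is retained iff it is a moderately expressed autosomal gene, has
    one or two annotated TSSs (i.e. a promoter window), and interacts with
    at least one TF; TFs on sex chromosomes are kept, but TFs with no
    retained hits (all-zero rows) are dropped.
    """
    expressed = set(expressed_genes)
    candidates = [
        g
        for g in promoters.windows
        if g in expressed and gene_chrom.get(g, "1") not in ("X", "Y")
    ]
    prior = pd.DataFrame(0, index=list(tf_ids), columns=candidates, dtype=float)
    for (tf, gene), hit_list in hits.items():
        if tf in prior.index and gene in prior.columns and len(hit_list) > 0:
            prior.loc[tf, gene] = 1.0
    prior = prior.loc[:, prior.sum(axis=0) > 0]
    prior = prior.loc[prior.sum(axis=1) > 0, :]
    if prior.size == 0:
        raise ValueError("empty motif prior")
    return prior


# --- coexpression -------------------------------------------------------


def coexpression(X: np.ndarray) -> np.ndarray:
    """Pearson correlation across cells (genes x genes).

    Constant genes get correlation 0 with everything and 1 on the diagonal.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need >= 3 cells for coexpression")
    sd = X.std(axis=1)
    ok = sd > 0
    C = np.zeros((X.shape[0], X.shape[0]))
    if ok.sum() >= 2:
        C_ok = np.corrcoef(X[ok])
        C[np.ix_(ok, ok)] = C_ok
    np.fill_diagonal(C, 1.0)
    return C


# --- PANDA --------------------------------------------------------------


def _panda_normalize(M: np.ndarray) -> np.ndarray:
    """Average of row-wise and column-wise z-scores scaled by 1/sqrt(2)."""
    mu_all = M.mean()
    sd_all = M.std()
    sd_all = sd_all if sd_all > 0 else 1.0
    rm = M.mean(axis=1, keepdims=True)
    rs = M.std(axis=1, keepdims=True)
    cm = M.mean(axis=0, keepdims=True)
    cs = M.std(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        zr = (M - rm) / rs
        zc = (M - cm) / cs
    z0 = (M - mu_all) / sd_all
    zr = np.where(np.isfinite(zr), zr, z0)
    zc = np.where(np.isfinite(zc), zc, z0)
    return (zr + zc) / np.sqrt(2.0)


def tanimoto(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Continuous Tanimoto similarity between rows of x and columns of y."""
    a = x @ y
    xn = (x**2).sum(axis=1)[:, None]
    yn = (y**2).sum(axis=0)[None, :]
    denom = xn + yn - np.abs(a)
    return a / np.sqrt(denom)


def _update_diagonal(M: np.ndarray, num: int, alpha: float, step: int) -> np.ndarray:
    M = M.copy()
    np.fill_diagonal(M, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        diag_std = np.nanstd(M, axis=1)
    np.fill_diagonal(M, diag_std * num * np.exp(2 * alpha * step))
    return M


@dataclass
class PandaNetwork:
    tf_ids: list[str]
    gene_ids: list[str]
    W: np.ndarray  # TF x gene edge Z-scores
    n_iter: int
    converged: bool
    trace: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=self.tf_ids, columns=self.gene_ids)


class PandaInference(BaseEstimator):
    """PANDA message-passing network inference (sklearn-style estimator).

    ``fit(prior, ppi=..., coexpr=...)`` stores the inferred edge matrix in
    ``network_``.  With ``alpha = 0`` the output equals the normalized
    prior (no-update limit).  Set ``normalize=False`` to feed matrices that
    are already on the z-score scale.
    """

    def __init__(self, alpha: float = 0.1, tol: float = 1e-3,
                 max_iter: int = 200, normalize: bool = True):
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter
        self.normalize = normalize

    def fit(self, prior: np.ndarray, *, ppi: np.ndarray, coexpr: np.ndarray):
        W = np.asarray(prior, dtype=float)
        P = np.asarray(ppi, dtype=float)
        C = np.asarray(coexpr, dtype=float)
        if np.any(~np.isfinite(W)) or np.any(~np.isfinite(P)) or np.any(~np.isfinite(C)):
            raise ValueError("NaN/inf in PANDA inputs")
        nt, ng = W.shape
        if P.shape != (nt, nt) or C.shape != (ng, ng):
            raise ValueError("dimension mismatch between prior, PPI and coexpression")
        if self.normalize:
            W = _panda_normalize(W)
            P = _panda_normalize(P)
            C = _panda_normalize(C)
        alpha = self.alpha
        trace: list[float] = []
        converged = False
        step = 0
        for step in range(self.max_iter):
            R = tanimoto(P, W)
            A = tanimoto(W, C)
            W_hat = (R + A) / 2.0
            hamming = float(np.abs(W - W_hat).mean())
            trace.append(hamming)
            W = (1 - alpha) * W + alpha * W_hat
            if hamming < self.tol:
                converged = True
                break
            ppi_new = _update_diagonal(tanimoto(W, W.T), ng, alpha, step)
            P = (1 - alpha) * P + alpha * ppi_new
            co_new = _update_diagonal(tanimoto(W.T, W), nt, alpha, step)
            C = (1 - alpha) * C + alpha * co_new
        if not converged:
            warnings.warn("PANDA did not converge", stacklevel=2)
        self.network_ = W
        self.n_iter_ = step + 1
        self.converged_ = converged
        self.trace_ = trace
        return self


def panda_infer(
    prior: pd.DataFrame,
    ppi: PPIMatrix | np.ndarray,
    coexpr: np.ndarray,
    alpha: float = 0.1,
    tol: float = 1e-3,
    max_iter: int = 200,
    normalize: bool = True,
) -> PandaNetwork:
    ppi_mat = ppi.scores if isinstance(ppi, PPIMatrix) else np.asarray(ppi)
    est = PandaInference(alpha=alpha, tol=tol, max_iter=max_iter, normalize=normalize)
    est.fit(prior.to_numpy(dtype=float), ppi=ppi_mat, coexpr=coexpr)
    return PandaNetwork(
        tf_ids=list(prior.index), gene_ids=list(prior.columns), W=est.network_,
        n_iter=est.n_iter_, converged=est.converged_, trace=est.trace_,
    )


# --- jackknife ensembles ------------------------------------------------


@dataclass
class NetworkEnsemble:
    condition: str  # "F" or "M"
    networks: list  # of PandaNetwork
    cell_subsets: list  # list of cell-id arrays
    seed: int

    def stack(self) -> np.ndarray:
        return np.stack([n.W for n in self.networks])


def jackknife_ensembles(
    nm: NormalizedMatrix,
    prior: pd.DataFrame,
    ppi: PPIMatrix,
    cfg: AnalysisConfig | None = None,
    seed: int = 0,
    sex: np.ndarray | None = None,
) -> tuple[NetworkEnsemble, NetworkEnsemble]:
    """Build sex-specific jackknife PANDA ensembles.

    For each sex, ``n_networks`` subsets of ``cells_per_network`` cells are
    sampled (without replacement within a subset, independently across
    subsets); coexpression is computed per subset and one PANDA network is
    inferred per subset.  Reproducible given the seed.
    """
    cfg = cfg or AnalysisConfig()
    sex = np.asarray(sex if sex is not None else nm.sex)
    gene_order = [g for g in prior.columns]
    sub = nm.subset(genes=gene_order)
    ensembles = []
    for si, s in enumerate(("F", "M")):
        cells = np.flatnonzero(sex == s)
        if cells.size < cfg.cells_per_network:
            raise ValueError(f"sex {s} has fewer than {cfg.cells_per_network} cells")
        rng = np.random.default_rng(seed + 7919 * si)
        nets, subsets = [], []
        for _ in range(cfg.n_networks):
            pick = rng.choice(cells, size=cfg.cells_per_network, replace=False)
            C = coexpression(sub.values[:, pick])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                net = panda_infer(
                    prior, ppi, C, alpha=cfg.panda_alpha, tol=cfg.panda_tol,
                    max_iter=cfg.panda_max_iter,
                )
            nets.append(net)
            subsets.append(nm.cell_ids[pick])
        ensembles.append(
            NetworkEnsemble(condition=s, networks=nets, cell_subsets=subsets, seed=seed)
        )
    return ensembles[0], ensembles[1]


# --- differential edges / degrees ---------------------------------------


def differential_edges(
    ens_f: NetworkEnsemble, ens_m: NetworkEnsemble,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Welch's t per edge on ensemble Z-scores, BH across retained edges.

    Edges with negative mean score in both ensembles are discarded before
    testing (non-existent regulation); the rest are significant iff
    FDR < ``edge_fdr`` and |mean difference| > ``edge_diff``.
    """
    cfg = cfg or AnalysisConfig()
    WF = ens_f.stack()
    WM = ens_m.stack()
    if WF.shape != WM.shape:
        raise ValueError("ensemble dimensions differ")
    mean_f = WF.mean(axis=0)
    mean_m = WM.mean(axis=0)
    keep = ~((mean_f < 0) & (mean_m < 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(WF, WM, axis=0, equal_var=False)
    tf_ids = ens_f.networks[0].tf_ids
    gene_ids = ens_f.networks[0].gene_ids
    ti, gi = np.nonzero(keep)
    table = pd.DataFrame(
        {
            "tf": [tf_ids[i] for i in ti],
            "gene": [gene_ids[j] for j in gi],
            "mean_F": mean_f[keep],
            "mean_M": mean_m[keep],
            "t": t[keep],
            "p": p[keep],
        }
    )
    table["p"] = table["p"].fillna(1.0)
    table["fdr"] = bh_fdr(table["p"].to_numpy())
    diff = (table["mean_F"] - table["mean_M"]).abs()
    table["diff"] = table["mean_F"] - table["mean_M"]
    table["significant"] = (table["fdr"] < cfg.edge_fdr) & (diff > cfg.edge_diff)
    table["direction"] = np.where(table["mean_F"] > table["mean_M"], "F", "M")
    return table


def differential_degrees(
    ens_f: NetworkEnsemble, ens_m: NetworkEnsemble, mode: str = "out",
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Welch's t on per-network active-edge degree sums.

    Active edges have positive mean score in at least one ensemble.  Out-
    degree sums a network's active-edge weights per TF; in-degree per gene.
    Significant iff FDR < ``degree_fdr`` and |mean difference| >
    ``degree_diff``.
    """
    if mode not in ("out", "in"):
        raise ValueError("mode must be 'out' or 'in'")
    cfg = cfg or AnalysisConfig()
    WF = ens_f.stack()
    WM = ens_m.stack()
    active = (WF.mean(axis=0) > 0) | (WM.mean(axis=0) > 0)
    axis = 2 if mode == "out" else 1
    deg_f = (WF * active).sum(axis=axis)  # n_networks x nodes
    deg_m = (WM * active).sum(axis=axis)
    ids = ens_f.networks[0].tf_ids if mode == "out" else ens_f.networks[0].gene_ids
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(deg_f, deg_m, axis=0, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    table = pd.DataFrame(
        {
            "id": ids,
            "mean_F": deg_f.mean(axis=0),
            "mean_M": deg_m.mean(axis=0),
            "t": t,
            "p": p,
        }
    )
    table["fdr"] = bh_fdr(table["p"].to_numpy())
    diff = (table["mean_F"] - table["mean_M"]).abs()
    table["significant"] = (table["fdr"] < cfg.degree_fdr) & (diff > cfg.degree_diff)
    table["direction"] = np.where(table["mean_F"] > table["mean_M"], "F", "M")
    return table.set_index("id")
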