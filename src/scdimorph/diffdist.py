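"""Differential-distribution classification of between-sex expression.

Each gene is screened by a two-sample Kolmogorov-Smirnov test on its
normalized expression (BH-adjusted across genes within the cell type);
significant genes are classified by comparing the modality of the
log-transformed nonzero expression in each sex:

* both unimodal -> DE candidate, finalized when the KS FDR ranks within the
  smallest 3% of all tested genes AND the absolute difference of
  log10 library-size-scaled means exceeds 0.2 (~1.5-fold);
* modality differs with exactly one overlapping component pair -> DM;
* modality differs with no overlapping component -> DB;
* both bimodal with matched components but significantly different mixing
  proportions -> DP;
* anything else significant -> NC.

Differential proportion of zeros (DZ) is assessed orthogonally by logistic
regression of the zero indicator on sex, adjusting for each cell's
detection rate, with a likelihood-ratio chi-square test (FDR < 0.025).

Modality is fitted by 1-vs-2-component Gaussian mixtures selected by BIC
(a deterministic finite-mixture stand-in for a Dirichlet-process partition;
every category definition only uses modality in {1, 2}).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.mixture import GaussianMixture

from .config import AnalysisConfig
from .datatypes import CountMatrix, NormalizedMatrix
from .stats import bh_fdr, ks_test

__all__ = [
    "ks_screen",
    "fit_modality",
    "ModalityFit",
    "classify_dd",
    "dz_test",
    "call_de",
    "run_diffdist",
]


def ks_screen(nm: NormalizedMatrix, sex: np.ndarray | None = None) -> pd.DataFrame:
    """Per-gene two-sample KS between sexes with BH adjustment across genes."""
    sex = np.asarray(sex if sex is not None else nm.sex)
    f = sex == "F"
    m = sex == "M"
    if f.sum() < 2 or m.sum() < 2:
        raise ValueError("need >= 2 cells of each sex")
    D = np.empty(nm.values.shape[0])
    p = np.empty(nm.values.shape[0])
    for g in range(nm.values.shape[0]):
        D[g], p[g] = ks_test(nm.values[g, f], nm.values[g, m])
    return pd.DataFrame(
        {"ks_D": D, "ks_p": p, "ks_fdr": bh_fdr(p)},
        index=pd.Index(nm.gene_ids, name="gene_id"),
    )


@dataclass
class ModalityFit:
    k: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    assignments: np.ndarray  # hard component label per value (components by mean)
    low_confidence: bool = False


def fit_modality(values: np.ndarray, min_nonzero: int = 10, seed: int = 0) -> ModalityFit:
    """Choose 1 vs 2 Gaussian components on log nonzero expression by BIC."""
    v = np.asarray(values, dtype=float).reshape(-1, 1)
    if v.shape[0] < min_nonzero:
        mu = float(v.mean()) if v.size else 0.0
        sd = float(v.std()) if v.size else 1.0
        return ModalityFit(
            k=1, means=np.array([mu]), sds=np.array([max(sd, 1e-3)]),
            weights=np.array([1.0]), assignments=np.zeros(v.shape[0], dtype=int),
            low_confidence=True,
        )
    fits = {}
    for k in (1, 2):
        # variance ridge of 0.04 (sd floor 0.2 log-units): absorbs count
        # discreteness so near-duplicate values cannot form a spurious mode
        gm = GaussianMixture(
            n_components=k, covariance_type="diag", reg_covar=0.04,
            n_init=5, random_state=seed, max_iter=200,
        ).fit(v)
        fits[k] = (gm.bic(v), gm)
    k = 1 if fits[1][0] <= fits[2][0] else 2
    gm = fits[k][1]
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_[order]
    raw = gm.predict(v)
    remap = np.empty_like(order)
    remap[order] = np.arange(k)
    return ModalityFit(
        k=k, means=means, sds=sds, weights=weights, assignments=remap[raw]
    )


def _overlaps(m1: float, s1: float, m2: float, s2: float) -> bool:
    pooled = np.sqrt((s1**2 + s2**2) / 2.0)
    return abs(m1 - m2) <= pooled


def _two_proportion_p(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-proportion z-test (pooled) on component-2 membership counts."""
    p1, p2 = k1 / n1, k2 / n2
    pool = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0
    z = (p1 - p2) / se
    return float(2 * sps.norm.sf(abs(z)))


def classify_dd(
    screen: pd.DataFrame,
    fits_f: dict[str, ModalityFit],
    fits_m: dict[str, ModalityFit],
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Assign each screened gene a DD category from its modality fits.

    Genes with KS FDR >= ``dd_fdr`` are NS.  Significant genes with both
    sexes unimodal become DE candidates (finalized by :func:`call_de`);
    the rest follow the DM / DB / DP / NC rules.
    """
    cfg = cfg or AnalysisConfig()
    rows = []
    for gene in screen.index:
        fdr = screen.loc[gene, "ks_fdr"]
        row = {"gene_id": gene, "category": "NS", "modality_F": np.nan,
               "modality_M": np.nan}
        if fdr < cfg.dd_fdr:
            ff = fits_f[gene]
            fm = fits_m[gene]
            row["modality_F"] = ff.k
            row["modality_M"] = fm.k
            if ff.k == 1 and fm.k == 1:
                row["category"] = "DE_candidate"
            elif ff.k != fm.k:
                uni, bi = (ff, fm) if ff.k == 1 else (fm, ff)
                n_overlap = sum(
                    _overlaps(uni.means[0], uni.sds[0], bi.means[j], bi.sds[j])
                    for j in range(2)
                )
                row["category"] = {0: "DB", 1: "DM"}.get(n_overlap, "NC")
            else:  # both bimodal
                matched = all(
                    _overlaps(ff.means[j], ff.sds[j], fm.means[j], fm.sds[j])
                    for j in range(2)
                )
                if matched:
                    k1 = int((ff.assignments == 1).sum())
                    k2 = int((fm.assignments == 1).sum())
                    p = _two_proportion_p(k1, ff.assignments.size, k2, fm.assignments.size)
                    row["category"] = "DP" if p < 0.05 else "NC"
                    row["dp_p"] = p
                else:
                    row["category"] = "NC"
        rows.append(row)
    out = pd.DataFrame(rows).set_index("gene_id")
    return screen.join(out.drop(columns=[]), how="left")


def dz_test(cm: CountMatrix, sex: np.ndarray | None = None,
            cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Differential proportion of zeros by logistic regression.

    Per gene, the zero indicator is regressed on sex plus the per-cell
    detection rate (proportion of actively expressed genes); a likelihood-
    ratio chi-square test of the sex coefficient is BH-adjusted across
    genes.  All-zero and all-nonzero genes are skipped.  Fitting goes
    through binomial IRLS, which degrades gracefully under separation.
    """
    cfg = cfg or AnalysisConfig()
    sex = np.asarray(sex if sex is not None else cm.sex)
    is_m = (sex == "M").astype(float)
    detect = (cm.counts > 0).mean(axis=0)
    pvals = np.full(cm.n_genes, np.nan)
    tested = np.zeros(cm.n_genes, dtype=bool)
    zero_f = np.full(cm.n_genes, np.nan)
    zero_m = np.full(cm.n_genes, np.nan)
    X_full = sm.add_constant(np.column_stack([is_m, detect]))
    X_red = sm.add_constant(detect)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for g in range(cm.n_genes):
            y = (cm.counts[g] == 0).astype(float)
            zero_f[g] = y[sex == "F"].mean()
            zero_m[g] = y[sex == "M"].mean()
            if y.sum() == 0 or y.sum() == y.size:
                continue
            try:
                full = sm.GLM(y, X_full, family=sm.families.Binomial()).fit()
                red = sm.GLM(y, X_red, family=sm.families.Binomial()).fit()
                lr = max(red.deviance - full.deviance, 0.0)
                pvals[g] = sps.chi2.sf(lr, 1)
                tested[g] = True
            except Exception:
                continue
    out = pd.DataFrame(
        {"zero_prop_F": zero_f, "zero_prop_M": zero_m, "dz_p": pvals},
        index=pd.Index(cm.gene_ids, name="gene_id"),
    )
    out["dz_fdr"] = np.nan
    out.loc[tested, "dz_fdr"] = bh_fdr(pvals[tested])
    out["is_DZ"] = out["dz_fdr"] < cfg.dz_fdr
    return out


def call_de(table: pd.DataFrame, cm: CountMatrix,
            cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Finalize DE candidates with the rank and fold-change criteria.

    A candidate becomes DE iff its KS FDR lies within the smallest
    ``de_fdr_quantile`` fraction of all tested genes (inclusive of ties at
    the quantile value) and the absolute difference of log10 library-size-
    scaled mean expression between sexes strictly exceeds ``de_log10_diff``
    (10^0.2 ~ 1.5-fold).  Zero means are guarded by epsilon = 1 / max
    library size.
    """
    cfg = cfg or AnalysisConfig()
    totals = cm.counts.sum(axis=0)
    eps = 1.0 / totals.max()
    scaled = cm.counts / totals
    f = cm.sex == "F"
    m = cm.sex == "M"
    mean_f = scaled[:, f].mean(axis=1)
    mean_m = scaled[:, m].mean(axis=1)
    lg_f = np.log10(mean_f + eps)
    lg_m = np.log10(mean_m + eps)
    diff = np.abs(lg_f - lg_m)
    gene_order = pd.Index(cm.gene_ids)
    table = table.copy()
    table["log10_mean_F"] = pd.Series(lg_f, index=gene_order).reindex(table.index)
    table["log10_mean_M"] = pd.Series(lg_m, index=gene_order).reindex(table.index)
    table["log10_diff"] = pd.Series(diff, index=gene_order).reindex(table.index)
    cutoff = np.quantile(table["ks_fdr"].to_numpy(), cfg.de_fdr_quantile)
    cand = table["category"] == "DE_candidate"
    is_de = cand & (table["ks_fdr"] <= cutoff) & (table["log10_diff"] > cfg.de_log10_diff)
    table.loc[cand, "category"] = np.where(is_de[cand], "DE", "NC")
    return table


def run_diffdist(
    nm: NormalizedMatrix,
    cm: CountMatrix,
    cfg: AnalysisConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Full per-cell-type differential-distribution analysis.

    ``nm`` supplies the normalized values for screening and modality
    fitting; ``cm`` supplies the counts (imputed, un-normalized) for the DE
    fold-change criterion and the DZ zero-proportion test.  Returns one row
    per gene with the KS screen, category, modality and DZ columns.
    """
    cfg = cfg or AnalysisConfig()
    screen = ks_screen(nm)
    f_mask = nm.sex == "F"
    m_mask = nm.sex == "M"
    fits_f: dict[str, ModalityFit] = {}
    fits_m: dict[str, ModalityFit] = {}
    sig = screen.index[screen["ks_fdr"] < cfg.dd_fdr]
    pos = {g: i for i, g in enumerate(nm.gene_ids)}
    for gene in sig:
        row = nm.values[pos[gene]]
        vf = row[f_mask]
        vm = row[m_mask]
        fits_f[gene] = fit_modality(vf[vf > 0], seed=seed)
        fits_m[gene] = fit_modality(vm[vm > 0], seed=seed)
    table = classify_dd(screen, fits_f, fits_m, cfg)
    table = call_de(table, cm, cfg)
    dz = dz_test(cm, cfg=cfg)
    return table.join(dz, how="left")


def dd_gene_ids(table: pd.DataFrame) -> list[str]:
    """Union of DM, DP, DB, DZ and NC genes (the 'DD genes')."""
    cats = table["category"].isin(["DM", "DP", "DB", "NC"])
    dz = table.get("is_DZ")
    mask = cats | (dz.fillna(False) if dz is not None else False)
    return list(table.index[mask])
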