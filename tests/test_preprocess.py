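"""QC, imputation, normalization, batch correction and gene/cell selection."""

import warnings

import numpy as np
import pytest

from scdimorph.config import AnalysisConfig
from scdimorph.datatypes import NormalizedMatrix
from scdimorph.preprocess import (
    HVGSelector,
    MNNCorrector,
    embedding_consistency_filter,
    fit_nb,
    impute_dropouts,
    library_balance_check,
    lognormalize,
    mnn_correct,
    nb_loglik_compare,
    qc_filter,
    select_hvgs,
)

from conftest import make_count_matrix, make_normalized


def small_cfg(**kw):
    kw.setdefault("min_genes_per_cell", 2)
    kw.setdefault("min_counts_per_cell", 10)
    kw.setdefault("gene_detect_count", 5)
    kw.setdefault("gene_detect_cells", 2)
    return AnalysisConfig(**kw)


# --- QC -----------------------------------------------------------------

def test_qc_cell_thresholds_inclusive():
    cfg = AnalysisConfig(gene_detect_cells=1)
    # build 600 genes so the detected-gene thresholds are reachable
    n_genes = 600
    counts = np.zeros((n_genes, 3))
    counts[:499, 0] = 120  # 499 detected genes -> removed (needs >= 500)
    counts[:500, 1] = 100  # 500 genes, exactly 50,000 counts -> retained
    counts[:520, 2] = 200  # comfortably retained
    cm = make_count_matrix(counts, sex=["F", "M", "F"])
    out, report = qc_filter(cm, cfg)
    assert list(report.cells_removed.index) == ["c0"]
    assert report.cells_removed.loc["c0", "reason"] == "low_genes"
    assert "c1" in out.cell_ids  # inclusive >= 50,000 bound


def test_qc_rrna_subtracted_from_totals_only():
    cfg = AnalysisConfig(gene_detect_cells=1)
    n_genes = 600
    counts = np.zeros((n_genes, 2))
    counts[1:501, 0] = 100  # exactly 50,000 without rRNA
    counts[1:501, 1] = 100
    cm = make_count_matrix(counts, gene_ids=["Rn45s"] + [f"g{i}" for i in range(n_genes - 1)])
    # cell 0's Rn45s counts must not contribute to its total
    cm.counts[0, 0] = 10_000
    out, report = qc_filter(cm, cfg)
    assert "c0" in out.cell_ids and "c1" in out.cell_ids
    assert report.post_rrna_totals["c0"] == pytest.approx(50_000)
    assert "Rn45s" not in out.gene_ids  # dropped from analysis


def test_qc_gene_detection_and_chry():
    cfg = small_cfg()
    counts = np.array(
        [
            [5, 5, 5, 0],   # detected >=5 in 3 cells -> kept
            [5, 5, 0, 0],   # exactly 2 cells -> kept (inclusive)
            [5, 0, 0, 0],   # 1 cell -> removed
            [4, 4, 4, 4],   # never reaches count 5 -> removed
            [9, 9, 9, 9],   # chrY -> removed
            [9, 9, 9, 9],
        ],
        dtype=float,
    )
    cm = make_count_matrix(counts, chrom=["1", "1", "1", "1", "Y", "2"])
    out, report = qc_filter(cm, cfg)
    assert set(out.gene_ids) == {"g0", "g1", "g5"}
    assert report.genes_removed.loc["g4", "reason"] == "chrY"
    assert report.genes_removed.loc["g2", "reason"] == "undetected"


def test_qc_idempotent():
    rng = np.random.default_rng(0)
    cm = make_count_matrix(rng.poisson(8, (30, 12)))
    cfg = small_cfg()
    once, _ = qc_filter(cm, cfg)
    twice, rep = qc_filter(once, cfg)
    assert np.array_equal(once.counts, twice.counts)
    assert rep.cells_removed.empty and rep.genes_removed.empty


# --- lognormalize -------------------------------------------------------

def test_lognormalize_closed_form_and_zero():
    counts = np.zeros((2, 1))
    counts[0, 0] = 100
    counts[1, 0] = 100_000 - 100
    nm = lognormalize(make_count_matrix(counts, sex=["F"]))
    assert nm.values[0, 0] == pytest.approx(np.log(100 / 1e5 * 1e4 + 1))  # ln(11)
    zero = make_count_matrix([[0, 3], [5, 2]])
    assert lognormalize(zero).values[0, 0] == 0.0


def test_lognormalize_scale_invariance_and_monotonicity(rng):
    counts = rng.poisson(10, (20, 4)) + 1.0
    nm1 = lognormalize(make_count_matrix(counts))
    nm2 = lognormalize(make_count_matrix(2 * counts))
    assert np.allclose(nm1.values, nm2.values)
    # strictly monotone per cell
    col = counts[:, 0]
    v = nm1.values[:, 0]
    order = np.argsort(col)
    assert np.all(np.diff(v[order]) >= 0)


def test_lognormalize_all_zero_cell_errors():
    with pytest.raises(ValueError, match="all-zero"):
        lognormalize(make_count_matrix([[0, 1], [0, 2]]))


# --- imputation ---------------------------------------------------------

@pytest.fixture(scope="module")
def imputed_pair():
    rng = np.random.default_rng(1)
    n_g, n_c = 25, 40
    mu = np.exp(rng.normal(3.2, 0.3, n_g))
    counts = rng.poisson(np.tile(mu[:, None], (1, n_c))).astype(float)
    # plant dropouts: zero out an expressed gene in a few cells
    counts[0] = rng.poisson(80, n_c)
    dropped = [0, 1, 2, 3]
    counts[0, dropped] = 0
    cm = make_count_matrix(counts)
    imp, model = impute_dropouts(cm, n_subpops=1, threshold=0.5, seed=0)
    return cm, imp, model, dropped


def test_impute_below_threshold_unchanged(imputed_pair):
    cm, imp, model, _ = imputed_pair
    mask = model.dropout_prob <= 0.5
    assert np.allclose(imp.counts[mask], cm.counts[mask])
    assert np.all(imp.counts >= 0)


def test_impute_restores_planted_dropouts(imputed_pair):
    cm, imp, model, dropped = imputed_pair
    assert np.all(model.dropout_prob[0, dropped] > 0.5)
    assert np.all(imp.counts[0, dropped] > 0)


def test_impute_pure_normal_gene_untouched(imputed_pair):
    # genes drawn from a tight unimodal law get lambda ~ 0: nothing imputed
    cm, imp, model, _ = imputed_pair
    lam = model.params[(5, 0)]["lam"]
    assert lam < 0.3
    assert np.allclose(imp.counts[5], cm.counts[5])


def test_impute_rejects_tiny_subpopulations():
    cm = make_count_matrix(np.ones((5, 4)))
    with pytest.raises(ValueError, match="fewer than 3"):
        impute_dropouts(cm, n_subpops=2)


# --- NB likelihood ------------------------------------------------------

def test_nb_fit_close_to_truth(rng):
    from scipy.stats import nbinom

    theta, mu = 2.0, 10.0
    x = rng.negative_binomial(theta, theta / (theta + mu), 1000)
    mu_hat, theta_hat, ll = fit_nb(x)
    ll_true = nbinom.logpmf(x, theta, theta / (theta + mu)).sum()
    assert ll >= ll_true  # MLE dominates the true parameters on the sample
    assert abs(ll - ll_true) / abs(ll_true) < 0.01


def test_nb_compare_identical_matrices():
    rng = np.random.default_rng(3)
    cm = make_count_matrix(rng.poisson(6, (8, 30)) + 1)
    out = nb_loglik_compare(cm, cm)
    assert np.allclose(out["loglik_raw"], out["loglik_imputed"])


def test_nb_compare_zero_inflated_gene_improves():
    # for tight, well-expressed genes an excess of technical zeros is
    # irreconcilable with a single NB; restoring them raises the likelihood
    rng = np.random.default_rng(4)
    n_g, n_c = 30, 200
    theta, mu = 8.0, 20.0
    clean = rng.negative_binomial(theta, theta / (theta + mu), (n_g, n_c)).astype(float)
    zeroed = clean.copy()
    zeroed[rng.random((n_g, n_c)) < 0.3] = 0.0
    raw = make_count_matrix(zeroed)
    imputed = make_count_matrix(clean)
    out = nb_loglik_compare(raw, imputed)
    frac = (out["loglik_imputed"] > out["loglik_raw"]).mean()
    assert frac > 0.5


def test_nb_all_zero_gene_flagged():
    cm0 = make_count_matrix(np.vstack([np.zeros(10), np.ones(10)]))
    out = nb_loglik_compare(cm0, cm0)
    assert np.isnan(out.iloc[0]["loglik_raw"]) and out.iloc[0]["flagged"]


# --- MNN ----------------------------------------------------------------

def test_mnn_single_batch_identity(rng):
    X = rng.normal(2, 1, (10, 8))
    out = MNNCorrector(k=3).transform(X, batches=np.array(["b"] * 8))
    assert np.array_equal(out, X)


def test_mnn_identical_batches_near_zero_correction(rng):
    X = rng.normal(2, 1, (15, 30))
    Xcat = np.hstack([X, X])
    batches = np.array(["a"] * 30 + ["b"] * 30)
    out = MNNCorrector(k=5).transform(Xcat, batches=batches)
    # corrections stay far below the data scale (kernel smoothing over
    # neighbouring pairs leaves a small residual)
    assert np.abs(out - Xcat).max() < 0.1


def test_mnn_removes_planted_shift(rng):
    g, n = 40, 30
    base = rng.normal(3, 1, g)
    delta = rng.normal(0, 0.6, g)
    X1 = base[:, None] + rng.normal(0, 0.1, (g, n))
    X2 = base[:, None] + delta[:, None] + rng.normal(0, 0.1, (g, n))
    X = np.hstack([X1, X2])
    out = MNNCorrector(k=10).transform(X, batches=np.array(["a"] * n + ["b"] * n))
    resid = np.linalg.norm(out[:, :n].mean(1) - out[:, n:].mean(1))
    assert resid < 0.1 * np.linalg.norm(delta)


def test_mnn_wrapper_tracks_provenance(rng):
    counts = rng.poisson(20, (12, 10)) + 1
    nm = lognormalize(make_count_matrix(counts, batch=["a"] * 5 + ["b"] * 5))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = mnn_correct(nm, k=3)
    assert out.provenance[-1] == "mnn"


# --- HVG selection ------------------------------------------------------

def test_hvg_constant_and_high_mean_excluded(rng):
    n_c = 50
    values = np.vstack(
        [
            np.full(n_c, 1.0),              # constant: excluded
            np.full(n_c, 4.0),              # mean 4 > 3: excluded
            rng.normal(1.0, 1.5, n_c),      # variable: candidate
        ]
    )
    values = np.abs(values)
    sel = HVGSelector().fit(values)
    assert not sel.get_support()[0]
    assert not sel.get_support()[1]


def test_hvg_matches_brute_force_binned_zscores(rng):
    values = np.abs(rng.normal(1, 0.7, (40, 60)))
    values[5] *= 2.5  # high dispersion gene
    n_bins = 4
    sel = HVGSelector(n_bins=n_bins).fit(values)
    # brute-force recomputation
    mean = values.mean(1)
    var = values.var(1, ddof=1)
    disp = np.where(mean > 0, var / mean, 0)
    logd = np.where(disp > 0, np.log(disp), -np.inf)
    order = np.argsort(mean, kind="stable")
    bins = np.empty(len(mean), int)
    bins[order] = np.minimum(np.arange(len(mean)) * n_bins // len(mean), n_bins - 1)
    z = np.full(len(mean), -np.inf)
    for b in range(n_bins):
        m = (bins == b) & np.isfinite(logd)
        if m.sum():
            sd = logd[m].std()
            z[m] = (logd[m] - logd[m].mean()) / (sd if sd > 0 else 1.0)
    expect = (z > 0.5) & (mean > 0.0125) & (mean < 3)
    assert np.array_equal(sel.get_support(), expect)


def test_select_hvgs_returns_gene_ids(rng):
    nm = make_normalized(np.abs(rng.normal(1, 0.5, (20, 30))))
    hvgs = select_hvgs(nm)
    assert set(hvgs) <= set(nm.gene_ids)


# --- embedding consistency ----------------------------------------------

def test_embedding_single_type_no_removal(rng):
    nm = make_normalized(rng.normal(0, 1, (10, 20)))
    kept, removed = embedding_consistency_filter(nm, reps=2, seed=0)
    assert removed == [] and len(kept) == 20


def test_embedding_separated_clouds_keep_all_remove_planted(rng):
    n = 40
    X = np.vstack([rng.normal(0, 1, (n, 8)), rng.normal(15, 1, (n, 8))])
    labels = np.array(["A"] * n + ["B"] * n)
    labels_bad = labels.copy()
    labels_bad[0] = "B"  # cell 0 sits inside cloud A but is labelled B
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kept, removed = embedding_consistency_filter(
            make_normalized(X.T, cell_type=list(labels)), reps=3, seed=0
        )
        assert removed == []
        kept2, removed2 = embedding_consistency_filter(
            make_normalized(X.T, cell_type=list(labels_bad)), reps=3, seed=0
        )
    # the planted mislabel goes; its immediate neighbour may be dragged
    # along (its nearest neighbour IS the mislabelled cell)
    assert "c0" in removed2 and len(removed2) <= 2


# --- library balance ----------------------------------------------------

def test_library_balance_detects_doubling(rng):
    counts = rng.poisson(20, (30, 60)).astype(float)
    counts[:, 30:] *= 2  # male libraries doubled
    cm = make_count_matrix(counts, sex=["F"] * 30 + ["M"] * 30)
    out = library_balance_check(cm)
    assert out.loc["t", "D"] > 0.5 and out.loc["t", "p"] < 1e-3


def test_library_balance_identical_and_missing_sex(rng):
    counts = np.tile(rng.poisson(20, (10, 1)), (1, 12)).astype(float)
    cm = make_count_matrix(counts)
    assert library_balance_check(cm).loc["t", "D"] == 0.0
    cm_f = make_count_matrix(counts, sex=["F"] * 12)
    out = library_balance_check(cm_f)
    assert bool(out.loc["t", "skipped"])
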