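"""Promoters, PWM scanning, PANDA inference and differential targeting."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from scdimorph.config import AnalysisConfig
from scdimorph.datatypes import PWM, PPIMatrix, TSSRecord
from scdimorph.regnet import (
    NetworkEnsemble,
    PandaNetwork,
    _log_odds,
    _panda_normalize,
    build_motif_prior,
    coexpression,
    define_promoters,
    differential_degrees,
    differential_edges,
    jackknife_ensembles,
    panda_infer,
    scan_pwm,
    tanimoto,
)


# --- promoters ----------------------------------------------------------

def test_single_tss_plus_strand_window():
    ps = define_promoters([TSSRecord("g", "1", 10_000, "+")])
    w = ps.windows["g"]
    assert (w["start"], w["end"]) == (9_250, 10_250)
    assert w["n_tss"] == 1


def test_double_tss_midpoint_window():
    ps = define_promoters(
        [TSSRecord("g", "1", 10_000, "+"), TSSRecord("g", "1", 11_000, "+")]
    )
    w = ps.windows["g"]
    assert (w["start"], w["end"]) == (9_500, 11_000)
    assert w["n_tss"] == 2


def test_minus_strand_mirrored():
    ps = define_promoters([TSSRecord("g", "1", 10_000, "-")])
    w = ps.windows["g"]
    assert (w["start"], w["end"]) == (9_750, 10_750)


def test_three_tss_gene_dropped_and_clipping():
    recs = [
        TSSRecord("multi", "1", p, "+") for p in (1_000, 2_000, 3_000)
    ] + [TSSRecord("edge", "1", 100, "+")]
    ps = define_promoters(recs)
    assert "multi" not in ps.windows and ps.dropped_genes == ["multi"]
    assert ps.windows["edge"]["start"] == 1 and "edge" in ps.clipped_genes


def test_promoter_totals_partition():
    recs = [TSSRecord("a", "1", 5_000, "+"), TSSRecord("b", "1", 9_000, "+"),
            TSSRecord("b", "1", 9_500, "+")]
    ps = define_promoters(recs)
    n_single = sum(1 for w in ps.windows.values() if w["n_tss"] == 1)
    n_double = sum(1 for w in ps.windows.values() if w["n_tss"] == 2)
    assert n_single + n_double == len(ps.windows)


# --- PWM scanning -------------------------------------------------------

def brute_force_pvals(pwm, background=None, pseudocount=0.1):
    """Exhaustive enumeration of window scores over all 4^L windows."""
    bg = np.asarray(background if background is not None else [0.25] * 4)
    lo = _log_odds(pwm, bg, pseudocount)
    scores = []
    for word in itertools.product(range(4), repeat=pwm.length):
        s = 0.0
        for j, b in enumerate(word):
            s += lo[b, j]
        scores.append(s)
    return np.array(scores)


def test_scan_pvalues_match_enumeration(rng):
    mat = rng.dirichlet([0.7, 0.7, 0.7, 0.7], size=5).T
    pwm = PWM("m", mat)
    seq = "".join(rng.choice(list("ACGT"), 60))
    all_scores = brute_force_pvals(pwm)
    hits = scan_pwm(seq, pwm, p_thresh=0.5)
    assert hits
    for h in hits:
        p_bf = (all_scores >= h.score).mean()
        assert h.p == pytest.approx(p_bf, rel=1e-10)


def test_scan_consensus_hit_only():
    # near-deterministic ACGT motif: only the consensus window scores at
    # p < 5e-5 (1/256 ~ 4e-3 would not suffice, so check the ranking)
    mat = np.full((4, 4), 0.01 / 3)
    for j, b in enumerate("ACGT"):
        mat["ACGT".index(b), j] = 0.99
    pwm = PWM("consensus", mat)
    seq = "TTTTTACGTTTTTT"
    hits = scan_pwm(seq, pwm, p_thresh=2 / 256)
    fwd = [h for h in hits if h.strand == "+"]
    assert len(fwd) == 1 and fwd[0].position == 5
    scores = brute_force_pvals(pwm)
    assert (scores >= fwd[0].score).sum() == 1  # consensus is the unique top


def test_scan_uniform_pwm_no_hits():
    pwm = PWM("uni", np.full((4, 4), 0.25))
    assert scan_pwm("ACGTACGTACGT", pwm, p_thresh=0.9) == []


def test_scan_handles_n_and_bad_chars():
    pwm = PWM("uni", np.full((4, 2), 0.25))
    assert scan_pwm("NNNN", pwm, p_thresh=1.1) == []  # N windows skipped
    with pytest.raises(ValueError, match="invalid"):
        scan_pwm("ACGX", pwm)
    with pytest.raises(ValueError, match="shorter"):
        scan_pwm("A", PWM("m", np.full((4, 3), 0.25)))


def test_scan_reverse_strand_position():
    mat = np.full((4, 4), 0.01 / 3)
    for j, b in enumerate("AACC"):
        mat["ACGT".index(b), j] = 0.99
    pwm = PWM("m", mat)
    # reverse complement of AACC is GGTT; plant it on the forward strand
    seq = "TTTGGTTTTT"
    hits = [h for h in scan_pwm(seq, pwm, p_thresh=2 / 256) if h.strand == "-"]
    assert len(hits) == 1 and hits[0].position == 3


# --- motif prior --------------------------------------------------------

def test_build_motif_prior_filters():
    promoters = define_promoters(
        [TSSRecord("gA", "1", 5000, "+"), TSSRecord("gB", "1", 9000, "+"),
         TSSRecord("gX", "X", 9000, "+"), TSSRecord("gC", "1", 12000, "+")]
    )
    hits = {("T1", "gA"): [1], ("T1", "gX"): [1], ("T2", "gB"): [1]}
    prior = build_motif_prior(
        hits, ["T1", "T2", "T3"], promoters,
        expressed_genes=["gA", "gB", "gX", "gC"],
        gene_chrom={"gA": "1", "gB": "1", "gX": "X", "gC": "1"},
    )
    assert "gX" not in prior.columns      # sex-chromosome gene dropped
    assert "gC" not in prior.columns      # no hits for any TF
    assert "T3" not in prior.index        # all-zero TF row dropped
    assert prior.to_numpy().sum() == 2


# --- coexpression -------------------------------------------------------

def test_coexpression_constant_gene_convention(rng):
    X = rng.normal(0, 1, (4, 10))
    X[2] = 5.0
    C = coexpression(X)
    assert C[2, 2] == 1.0
    assert np.allclose(C[2, [0, 1, 3]], 0.0)
    # non-constant entries match the direct formula
    direct = np.corrcoef(X[[0, 1, 3]])
    assert np.allclose(C[np.ix_([0, 1, 3], [0, 1, 3])], direct)


def test_coexpression_needs_three_cells(rng):
    with pytest.raises(ValueError):
        coexpression(rng.normal(0, 1, (3, 2)))


# --- PANDA --------------------------------------------------------------

def tanimoto_oracle(x, y):
    out = np.empty((x.shape[0], y.shape[1]))
    for i in range(x.shape[0]):
        for j in range(y.shape[1]):
            a = float(x[i] @ y[:, j])
            out[i, j] = a / np.sqrt((x[i] ** 2).sum() + (y[:, j] ** 2).sum() - abs(a))
    return out


def test_tanimoto_matches_elementwise_oracle(rng):
    x = rng.normal(0, 1, (3, 5))
    y = rng.normal(0, 1, (5, 4))
    assert np.allclose(tanimoto(x, y), tanimoto_oracle(x, y), rtol=1e-12)


def test_panda_alpha_zero_returns_normalized_prior():
    prior = pd.DataFrame([[1.0, 0, 1], [0, 1, 1]], index=["T1", "T2"],
                         columns=["a", "b", "c"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = panda_infer(prior, np.eye(2), np.eye(3), alpha=0.0, max_iter=3)
    assert np.allclose(net.W, _panda_normalize(prior.to_numpy()))


def test_panda_one_iteration_matches_hand_computed_update(rng):
    # hand-set, pre-normalized matrices; one step of the message passing
    W0 = rng.normal(0, 1, (2, 3))
    P0 = rng.normal(0, 1, (2, 2))
    P0 = (P0 + P0.T) / 2
    C0 = rng.normal(0, 1, (3, 3))
    C0 = (C0 + C0.T) / 2
    alpha = 0.1
    R = tanimoto_oracle(P0, W0)
    A = tanimoto_oracle(W0, C0)
    expected = (1 - alpha) * W0 + alpha * (R + A) / 2
    prior = pd.DataFrame(W0, index=["T1", "T2"], columns=list("abc"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = panda_infer(prior, P0, C0, alpha=alpha, max_iter=1, normalize=False)
    assert np.allclose(net.W, expected, rtol=1e-12)


def test_panda_duplicated_tf_rows_stay_identical(rng):
    prior = pd.DataFrame(
        [[1.0, 0, 1, 0], [1.0, 0, 1, 0], [0, 1, 0, 1]],
        index=["T1", "T1b", "T2"], columns=list("abcd"),
    )
    ppi = np.array([[1, 1, 0.2], [1, 1, 0.2], [0.2, 0.2, 1.0]])
    C = coexpression(rng.normal(0, 1, (4, 12)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = panda_infer(prior, ppi, C, max_iter=30)
    assert np.allclose(net.W[0], net.W[1], atol=1e-10)


def test_panda_convergence_metric_decreases(rng):
    prior = pd.DataFrame(
        (rng.random((4, 10)) < 0.4).astype(float),
        index=[f"T{i}" for i in range(4)], columns=[f"g{j}" for j in range(10)],
    )
    ppi = np.eye(4) * 0.9 + 0.1
    C = coexpression(rng.normal(0, 1, (10, 15)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = panda_infer(prior, ppi, C, max_iter=100)
    trace = np.array(net.trace)
    assert trace[-1] <= trace[2]  # non-increasing after burn-in


def test_panda_permutation_equivariance(rng):
    prior = pd.DataFrame(
        (rng.random((3, 6)) < 0.5).astype(float),
        index=["T0", "T1", "T2"], columns=[f"g{j}" for j in range(6)],
    )
    ppi = np.eye(3) * 0.8 + 0.2
    X = rng.normal(0, 1, (6, 20))
    C = coexpression(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = panda_infer(prior, ppi, C, max_iter=40)
        pt = [2, 0, 1]
        pg = [3, 1, 0, 5, 2, 4]
        prior2 = prior.iloc[pt, pg]
        net2 = panda_infer(prior2, ppi[np.ix_(pt, pt)], C[np.ix_(pg, pg)], max_iter=40)
    assert np.allclose(net.W[np.ix_(pt, pg)], net2.W, atol=1e-10)


def test_panda_rejects_nan_and_mismatch():
    prior = pd.DataFrame(np.ones((2, 3)), index=["a", "b"], columns=list("xyz"))
    with pytest.raises(ValueError, match="NaN"):
        panda_infer(prior, np.full((2, 2), np.nan), np.eye(3))
    with pytest.raises(ValueError, match="dimension"):
        panda_infer(prior, np.eye(3), np.eye(3))


# --- ensembles & differential tests -------------------------------------

def _toy_ensembles(rng, shift=0.0, n_nets=30, nt=2, ng=3):
    """Synthetic Z-score ensembles (bypasses PANDA for speed)."""
    def build(mu):
        nets = [
            PandaNetwork(
                tf_ids=[f"T{i}" for i in range(nt)],
                gene_ids=[f"g{j}" for j in range(ng)],
                W=mu + rng.normal(0, 0.05, (nt, ng)),
                n_iter=1, converged=True,
            )
            for _ in range(n_nets)
        ]
        return nets

    muF = np.arange(nt * ng).reshape(nt, ng) * 0.1
    muM = muF + shift
    ensF = NetworkEnsemble("F", build(muF), [], seed=0)
    ensM = NetworkEnsemble("M", build(muM), [], seed=0)
    return ensF, ensM


def test_differential_edges_identical_ensembles_null(rng):
    ensF, ensM = _toy_ensembles(rng, shift=0.0)
    out = differential_edges(ensF, ensM)
    assert out["significant"].sum() == 0


def test_differential_edges_discards_doubly_negative(rng):
    ensF, ensM = _toy_ensembles(rng)
    for net in ensF.networks:
        net.W[0, 0] = -0.3
    for net in ensM.networks:
        net.W[0, 0] = -0.2
    out = differential_edges(ensF, ensM)
    assert not ((out["tf"] == "T0") & (out["gene"] == "g0")).any()


def test_differential_edges_planted_shift_detected(rng):
    ensF, ensM = _toy_ensembles(rng, shift=0.0, n_nets=100)
    for net in ensM.networks:
        net.W[1, 2] += 0.5
    out = differential_edges(ensF, ensM).set_index(["tf", "gene"])
    assert bool(out.loc[("T1", "g2"), "significant"])
    assert out.loc[("T1", "g2"), "direction"] == "M"


def test_degree_sums_match_manual_addition():
    W1 = np.array([[1.0, -2.0], [3.0, 4.0]])
    W2 = np.array([[2.0, 1.0], [-1.0, 0.5]])
    nets_f = [PandaNetwork(["T0", "T1"], ["g0", "g1"], W1, 1, True)]
    nets_m = [PandaNetwork(["T0", "T1"], ["g0", "g1"], W2, 1, True)]
    ensF = NetworkEnsemble("F", nets_f, [], 0)
    ensM = NetworkEnsemble("M", nets_m, [], 0)
    # active mask: positive mean in >= 1 ensemble -> all edges except (0,1)?
    # edge (0,1): means -2 (F) and 1 (M) -> active; every edge is active
    out_deg = differential_degrees(ensF, ensM, "out")
    assert out_deg.loc["T0", "mean_F"] == pytest.approx(1.0 - 2.0)
    assert out_deg.loc["T1", "mean_F"] == pytest.approx(7.0)
    in_deg = differential_degrees(ensF, ensM, "in")
    assert in_deg.loc["g0", "mean_M"] == pytest.approx(2.0 - 1.0)
    # conservation: sum over out-degrees == sum over in-degrees
    assert out_deg["mean_F"].sum() == pytest.approx(in_deg["mean_F"].sum())


def test_differential_degrees_identical_null(rng):
    ensF, ensM = _toy_ensembles(rng)
    for mode in ("out", "in"):
        assert differential_degrees(ensF, ensM, mode)["significant"].sum() == 0


def test_jackknife_deterministic_and_subset_sizes(rng):
    from scdimorph.preprocess import lognormalize
    from conftest import make_count_matrix

    counts = rng.poisson(10, (15, 40)) + 1
    cm = make_count_matrix(counts, sex=["F"] * 20 + ["M"] * 20)
    nm = lognormalize(cm)
    prior = pd.DataFrame(
        (rng.random((3, 15)) < 0.4).astype(float),
        index=["T0", "T1", "T2"], columns=list(nm.gene_ids),
    )
    ppi = PPIMatrix(["T0", "T1", "T2"], np.eye(3) * 0.8 + 0.2)
    cfg = AnalysisConfig(n_networks=3, cells_per_network=10, panda_max_iter=30)
    e1f, e1m = jackknife_ensembles(nm, prior, ppi, cfg, seed=5)
    e2f, e2m = jackknife_ensembles(nm, prior, ppi, cfg, seed=5)
    for a, b in zip(e1f.networks, e2f.networks):
        assert np.array_equal(a.W, b.W)
    sexmap = dict(zip(cm.cell_ids, cm.sex))
    for subset in e1f.cell_subsets:
        assert len(subset) == 10 and all(sexmap[c] == "F" for c in subset)
    for subset in e1m.cell_subsets:
        assert len(subset) == 10 and all(sexmap[c] == "M" for c in subset)
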