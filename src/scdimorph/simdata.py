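"""Synthetic single-cell data with planted ground truth.

Two generators cover the pipeline's inputs:

* :func:`simulate_expression` draws negative-binomial read counts for two
  sexes over one or more cell types and batches, with technical dropout and
  planted differential-distribution genes of each category (DE, DM, DP, DB,
  DZ).
* :func:`simulate_regulation` draws counts from a latent TF-activity model
  with sex-specific regulatory strength on planted TF->gene edges, together
  with a motif prior (planted edges plus random decoys) and a TF-family PPI
  matrix, for exercising network inference.

:func:`emit_fixtures` materializes a full fixture directory (MTX counts,
metadata, GMT, MEME motifs, promoter FASTA with implanted motif hits, TSS
table, PPI, truth tables) through the package's own writers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as sio
from .datatypes import PWM, CountMatrix, GeneSetCollection, PPIMatrix, TSSRecord

DD_CATEGORIES = ("DE", "DM", "DP", "DB", "DZ")

_DEFAULT_CATEGORY_COUNTS = {"DE": 20, "DM": 20, "DP": 20, "DB": 20, "DZ": 20}


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    Defaults emulate FACS-sorted plate-based scRNA-seq of ~100 cells per sex:
    NB dispersion theta=3 (variance = mu + mu^2/3), moderate technical
    dropout decreasing with expression, a 2.5 natural-log DE shift (~12-fold,
    the near-binary magnitude of canonical sex-dimorphic genes — DE genes
    must by definition carry the most extreme signals in the transcriptome),
    bimodal components separated by 2.0 log-units, mixing proportions
    0.8/0.2 swapped across sexes for DP genes, and a 0.45 structural-zero
    excess in one sex for DZ genes.  Planted effects are placed on
    moderately expressed genes (base log-mean above the 30th percentile):
    distributional categories are undefined at the detection floor.
    Category effects are centred so they perturb total library size as
    little as possible (library-size normalization would otherwise leak a
    compositional shift into every null gene).
    """

    n_genes: int = 1000
    n_cells_per_sex: int = 100
    n_cell_types: int = 1
    n_batches: int = 2
    nb_dispersion: float = 3.0
    dropout_intercept: float = 0.5
    dropout_slope: float = 1.0
    category_counts: dict = field(default_factory=lambda: dict(_DEFAULT_CATEGORY_COUNTS))
    de_shift: float = 2.5
    bimodal_separation: float = 2.0
    dp_weight: float = 0.8
    dz_delta: float = 0.45
    base_logmean_mean: float = 2.0
    base_logmean_sd: float = 1.0
    celltype_sd: float = 0.5
    batch_sd: float = 0.2
    libsize_sd: float = 0.3
    # regulation scenario
    n_tfs: int = 10
    targets_per_tf: int = 20
    regulatory_signal: float = 1.0
    decoy_factor: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.category_counts.values()) > self.n_genes:
            raise ValueError("category counts exceed n_genes")
        if self.n_cells_per_sex < 1 or self.n_genes < 1:
            raise ValueError("need positive cell and gene counts")
        if self.regulatory_signal < 0:
            raise ValueError("regulatory_signal must be >= 0")
        unknown = set(self.category_counts) - set(DD_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown DD categories: {sorted(unknown)}")


@dataclass
class SimTruth:
    """Planted ground truth: per-gene DD table plus regulatory edges."""

    genes: pd.DataFrame  # index gene_id; dd_category, effect parameters
    planted_edges: list = field(default_factory=list)  # (tf, gene, sex_specific)
    tf_activity: dict = field(default_factory=dict)  # tf -> {"F": mult, "M": mult}


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p).astype(float)


def _make_obs(cfg: SimConfig) -> pd.DataFrame:
    cells, sexes = [], []
    for sex in ("F", "M"):
        for i in range(cfg.n_cells_per_sex):
            cells.append(f"{sex}{i:04d}")
            sexes.append(sex)
    n = len(cells)
    cell_types = [f"ct{i % cfg.n_cell_types}" for i in range(n)]
    batches = [f"b{(i // 2) % cfg.n_batches}" for i in range(n)]  # sex-balanced
    return pd.DataFrame(
        {"sex": sexes, "cell_type": cell_types, "batch": batches},
        index=pd.Index(cells, name="cell_id"),
    )


def simulate_expression(cfg: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Draw NB counts with technical dropout and planted DD genes.

    log mu_gc = gene base + cell-type offset + per-category sex effect +
    batch offset + log library factor; counts ~ NB(mu, theta); technical
    dropout zeroes entries with logistic probability decreasing in log mu.
    """
    rng = np.random.default_rng(cfg.seed)
    obs = _make_obs(cfg)
    n_cells = len(obs)
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    # chromosome labels: mostly autosomal, a few X to exercise filters
    chrom = np.where(np.arange(cfg.n_genes) % 50 == 49, "X", "1")
    var = pd.DataFrame({"chrom": chrom}, index=pd.Index(gene_ids, name="gene_id"))

    is_m = (obs["sex"] == "M").to_numpy()
    ct_codes = pd.Categorical(obs["cell_type"]).codes
    batch_codes = pd.Categorical(obs["batch"]).codes

    base = rng.normal(cfg.base_logmean_mean, cfg.base_logmean_sd, size=cfg.n_genes)
    ct_off = rng.normal(0.0, cfg.celltype_sd, size=(cfg.n_genes, cfg.n_cell_types))
    if cfg.n_cell_types == 1:
        ct_off[:] = 0.0
    batch_off = rng.normal(0.0, cfg.batch_sd, size=(cfg.n_genes, cfg.n_batches))
    lib = rng.lognormal(0.0, cfg.libsize_sd, size=n_cells)

    # planted categories go to random moderately expressed genes, planted
    # in base-sharing pairs with the affected sex alternating: a strong
    # multiplicative effect is one-sided in count space, and unpaired
    # planting would skew total library size between the sexes — an
    # artifact a full-size transcriptome dilutes but a desk-scale gene
    # panel does not
    eligible = np.flatnonzero(base > np.quantile(base, 0.3))
    order = rng.permutation(eligible)
    category = np.array(["NS"] * cfg.n_genes, dtype=object)
    effect_sex_arr = np.array([""] * cfg.n_genes, dtype=object)
    sign = np.zeros(cfg.n_genes)
    pos = 0
    for cat in DD_CATEGORIES:
        k = int(cfg.category_counts.get(cat, 0))
        genes = order[pos : pos + k]
        category[genes] = cat
        for i, g in enumerate(genes):
            effect_sex_arr[g] = "F" if i % 2 == 0 else "M"
            if cat == "DE":
                sign[g] = (
                    (1.0 if rng.random() < 0.5 else -1.0)
                    if i % 2 == 0
                    else sign[genes[i - 1]]  # pair shares the direction
                )
            if i % 2 == 1:
                base[g] = base[genes[i - 1]]
        pos += k

    logmu = (
        base[:, None]
        + ct_off[:, ct_codes]
        + batch_off[:, batch_codes]
        + np.log(lib)[None, :]
    )

    sep = cfg.bimodal_separation
    bimodal_sex = effect_sex_arr
    for g in np.flatnonzero(category != "NS"):
        cat = category[g]
        which = bimodal_sex[g]
        affected = is_m if which == "M" else ~is_m
        if cat == "DE":
            logmu[g, affected] += sign[g] * cfg.de_shift
        elif cat == "DM":
            # affected sex: mixture of base (shared component) and base + sep
            # (the extra component sits above base: a downward component is
            # eroded by dropout and stops being an identifiable mode)
            hi = affected & (rng.random(n_cells) < 0.5)
            logmu[g, hi] += sep
        elif cat == "DP":
            # both sexes bimodal at {base, base + sep}; proportions swapped
            p_hi = np.where(affected, cfg.dp_weight, 1.0 - cfg.dp_weight)
            hi = rng.random(n_cells) < p_hi
            logmu[g, hi] += sep
        elif cat == "DB":
            # affected sex bimodal at base +- 0.75*sep: no shared component
            hi = rng.random(n_cells) < 0.5
            logmu[g, affected] += np.where(hi, 0.75 * sep, -0.75 * sep)[affected]
        # DZ handled after count draw (structural zeros)

    mu = np.exp(logmu)
    counts = _nb_draw(rng, mu, cfg.nb_dispersion)

    # technical dropout, identical model for both sexes
    p_drop = _sigmoid(cfg.dropout_intercept - cfg.dropout_slope * np.log1p(mu))
    counts[rng.random(counts.shape) < p_drop] = 0.0

    for g in np.flatnonzero(category == "DZ"):
        affected = is_m if bimodal_sex[g] == "M" else ~is_m
        zero = affected & (rng.random(n_cells) < cfg.dz_delta)
        counts[g, zero] = 0.0

    truth_df = pd.DataFrame(
        {
            "dd_category": category,
            "effect_sex": bimodal_sex,
            "de_sign": sign,
            "shift": np.where(category == "DE", cfg.de_shift, 0.0),
            "separation": np.where(np.isin(category, ["DM", "DP", "DB"]), sep, 0.0),
            "dp_weight": np.where(category == "DP", cfg.dp_weight, np.nan),
            "dz_delta": np.where(category == "DZ", cfg.dz_delta, 0.0),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return CountMatrix(counts, obs, var), SimTruth(genes=truth_df)


def simulate_regulation(
    cfg: SimConfig, truth: SimTruth | None = None
) -> tuple[CountMatrix, pd.DataFrame, PPIMatrix, SimTruth]:
    """Draw counts from a latent TF-activity model with sex-specific edges.

    Per-cell TF activities are standard normal; gene log-means add
    ``beta * activity`` over the gene's regulators, where ``beta =
    regulatory_signal`` only in the sex an edge is specific to (both sexes
    for unspecific edges).  The motif prior contains every planted edge plus
    ``decoy_factor`` times as many random decoys; the PPI groups TFs into
    pairs with elevated within-family scores.
    """
    if cfg.n_tfs < 2:
        raise ValueError("need n_tfs >= 2")
    if cfg.targets_per_tf > cfg.n_genes:
        raise ValueError("targets_per_tf exceeds n_genes")
    rng = np.random.default_rng(cfg.seed + 1)
    obs = _make_obs(cfg)
    n_cells = len(obs)
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    tf_ids = [f"TF{i:02d}" for i in range(cfg.n_tfs)]
    var = pd.DataFrame(
        {"chrom": ["1"] * cfg.n_genes}, index=pd.Index(gene_ids, name="gene_id")
    )
    is_m = (obs["sex"] == "M").to_numpy()

    # planted edges; TF00 regulates only in females, TF01 only in males
    edges = []
    target_idx = np.zeros((cfg.n_tfs, cfg.targets_per_tf), dtype=int)
    for t in range(cfg.n_tfs):
        tgt = rng.choice(cfg.n_genes, size=cfg.targets_per_tf, replace=False)
        target_idx[t] = tgt
        spec = "F" if t == 0 else ("M" if t == 1 else "both")
        for g in tgt:
            edges.append((tf_ids[t], gene_ids[g], spec))

    activity = rng.normal(0.0, 1.0, size=(cfg.n_tfs, n_cells))
    base = rng.normal(cfg.base_logmean_mean, 0.5, size=cfg.n_genes)
    logmu = np.tile(base[:, None], (1, n_cells))
    for t in range(cfg.n_tfs):
        spec = "F" if t == 0 else ("M" if t == 1 else "both")
        if spec == "both":
            active = np.ones(n_cells, dtype=bool)
        else:
            active = is_m if spec == "M" else ~is_m
        beta = cfg.regulatory_signal
        contrib = beta * activity[t][None, :] * active[None, :]
        logmu[target_idx[t]] += contrib

    mu = np.exp(logmu)
    counts = _nb_draw(rng, mu, cfg.nb_dispersion)
    p_drop = _sigmoid(cfg.dropout_intercept - cfg.dropout_slope * np.log1p(mu))
    counts[rng.random(counts.shape) < p_drop] = 0.0

    # motif prior: planted edges + decoys
    prior = pd.DataFrame(0, index=tf_ids, columns=gene_ids, dtype=int)
    for tf, g, _ in edges:
        prior.loc[tf, g] = 1
    n_decoy = cfg.decoy_factor * len(edges)
    open_pairs = np.flatnonzero(prior.to_numpy().ravel() == 0)
    decoys = rng.choice(open_pairs, size=min(n_decoy, open_pairs.size), replace=False)
    flat = prior.to_numpy().ravel()
    flat[decoys] = 1
    prior = pd.DataFrame(
        flat.reshape(cfg.n_tfs, cfg.n_genes), index=tf_ids, columns=gene_ids
    )

    # PPI: TF pairs form families with elevated within-family scores
    scores = np.full((cfg.n_tfs, cfg.n_tfs), 0.05)
    for t in range(0, cfg.n_tfs - 1, 2):
        scores[t, t + 1] = scores[t + 1, t] = 0.8
    np.fill_diagonal(scores, 1.0)
    ppi = PPIMatrix(tf_ids=tf_ids, scores=scores)

    genes_df = (
        truth.genes
        if truth is not None
        else pd.DataFrame(
            {"dd_category": ["NS"] * cfg.n_genes},
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )
    out_truth = SimTruth(
        genes=genes_df,
        planted_edges=edges,
        tf_activity={
            tf_ids[0]: {"F": 1.0, "M": 0.0},
            tf_ids[1]: {"F": 0.0, "M": 1.0},
            **{t: {"F": 1.0, "M": 1.0} for t in tf_ids[2:]},
        },
    )
    return CountMatrix(counts, obs, var), prior, ppi, out_truth


# --- fixture emission ---------------------------------------------------

_CONSENSUS_MOTIFS = {"MOTIF_A": "ACGTACGT", "MOTIF_B": "TTGACCAA", "MOTIF_C": "GGGCGC"}


def _consensus_pwm(name: str, consensus: str, strength: float = 0.97) -> PWM:
    mat = np.full((4, len(consensus)), (1.0 - strength) / 3.0)
    for j, b in enumerate(consensus):
        mat["ACGT".index(b), j] = strength
    return PWM(name, mat)


def emit_fixtures(outdir: str, cfg: SimConfig | None = None) -> dict:
    """Write a complete fixture directory and return a manifest.

    Produces counts (MTX + sidecars), cell metadata, a GMT enriched for
    planted DD genes plus random sets, MEME PWMs with known consensus,
    promoter FASTA sequences with motif occurrences implanted at recorded
    offsets, a TSS table in which genes carry 1, 2 or 3 TSSs, a PPI TSV and
    truth tables.  Fixing ``cfg.seed`` fixes every emitted byte.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed + 2)
    sio.ensure_dir(outdir)
    cm, truth = simulate_expression(cfg)
    _, _, ppi, reg_truth = simulate_regulation(cfg, truth)

    counts_path = f"{outdir}/counts.mtx"
    meta_path = f"{outdir}/cells.meta.tsv"
    sio.write_counts(cm, counts_path, meta_path)

    # gene sets: one per planted category plus random decoy sets
    sets: dict[str, list[str]] = {}
    for cat in DD_CATEGORIES:
        genes = truth.genes.index[truth.genes["dd_category"] == cat].tolist()
        if genes:
            sets[f"planted_{cat}"] = genes
    for i in range(10):
        sets[f"random_{i}"] = list(
            rng.choice(cm.gene_ids, size=25, replace=False)
        )
    gmt_path = f"{outdir}/sets.gmt"
    sio.write_gmt(GeneSetCollection(sets), gmt_path)

    pwms = [_consensus_pwm(n, c) for n, c in _CONSENSUS_MOTIFS.items()]
    pwm_path = f"{outdir}/motifs.meme"
    sio.write_pwms(pwms, pwm_path)

    # promoters: random sequence with each consensus implanted once
    bases = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    occurrences = []
    promoter_genes = list(cm.gene_ids[:30])
    for gi, g in enumerate(promoter_genes):
        seq = list(rng.choice(bases, size=600))
        pwm = pwms[gi % len(pwms)]
        cons = pwm.consensus()
        off = int(rng.integers(0, 600 - len(cons)))
        seq[off : off + len(cons)] = list(cons)
        seqs[g] = "".join(seq)
        occurrences.append({"gene_id": g, "motif": pwm.name, "offset": off})
    fasta_path = f"{outdir}/promoters.fa"
    sio.write_fasta(seqs, fasta_path)

    # TSS table: genes cycle through 1, 2 and 3 distinct TSSs
    records = []
    for gi, g in enumerate(promoter_genes):
        n_tss = 1 + gi % 3
        start = 10_000 + 5_000 * gi
        strand = "+" if gi % 2 == 0 else "-"
        for k in range(n_tss):
            records.append(TSSRecord(gene_id=g, chrom="1", pos=start + 1_000 * k, strand=strand))
    tss_path = f"{outdir}/tss.tsv"
    sio.write_tss(records, tss_path)

    ppi_path = f"{outdir}/ppi.tsv"
    sio.write_ppi(ppi, ppi_path)

    truth_path = f"{outdir}/truth.genes.tsv"
    truth.genes.to_csv(truth_path, sep="\t")
    edges_path = f"{outdir}/truth.edges.tsv"
    pd.DataFrame(reg_truth.planted_edges, columns=["tf", "gene", "sex_specific"]).to_csv(
        edges_path, sep="\t", index=False
    )
    occ_path = f"{outdir}/truth.motif_occurrences.tsv"
    pd.DataFrame(occurrences).to_csv(occ_path, sep="\t", index=False)

    return {
        "counts": counts_path,
        "meta": meta_path,
        "gmt": gmt_path,
        "pwms": pwm_path,
        "fasta": fasta_path,
        "tss": tss_path,
        "ppi": ppi_path,
        "truth_genes": truth_path,
        "truth_edges": edges_path,
        "truth_motifs": occ_path,
        "occurrences": occurrences,
        "tss_records": records,
    }
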