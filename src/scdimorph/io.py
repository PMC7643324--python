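"""Readers and writers for the pipeline's file formats.

Counts come in as MatrixMarket triplets (with gene/cell sidecar files) or as
dense CSV/TSV; gene sets as GMT; motifs in MEME minimal format; TSS
annotations and TF-TF interaction scores as TSV.  Writers exist for every
format so simulated fixtures round-trip through the same code paths real
data would use.
"""

from __future__ import annotations

import os
import re

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import PWM, CountMatrix, GeneSetCollection, PPIMatrix, TSSRecord

__all__ = [
    "load_counts",
    "write_counts",
    "load_gmt",
    "write_gmt",
    "load_pwms",
    "write_pwms",
    "load_tss",
    "write_tss",
    "load_ppi",
    "write_ppi",
    "read_fasta",
    "write_fasta",
]

META_COLUMNS = ("sex", "cell_type", "batch")


def load_counts(path: str, meta_path: str) -> CountMatrix:
    """Load a gene x cell count matrix plus cell metadata.

    ``path`` may be a MatrixMarket file (``.mtx``; gene and cell ids are read
    from ``<stem>_genes.tsv`` / ``<stem>_cells.tsv`` sidecars) or a dense
    CSV/TSV with gene ids in the first column and cell ids in the header.
    ``meta_path`` is a TSV keyed by cell id with ``sex``, ``cell_type`` and
    ``batch`` columns, and optionally a gene metadata companion is not
    required: chromosome labels are read from a ``chrom`` column of the gene
    sidecar when present, else default to ``"1"``.
    """
    if path.endswith(".mtx"):
        mat = scipy.io.mmread(path)
        counts = np.asarray(scipy.sparse.coo_matrix(mat).todense(), dtype=float)
        stem = path[: -len(".mtx")]
        genes = pd.read_csv(stem + "_genes.tsv", sep="\t", index_col=0)
        cells = pd.read_csv(stem + "_cells.tsv", sep="\t", index_col=0)
        gene_ids = genes.index.astype(str)
        cell_ids = cells.index.astype(str)
        chrom = (
            genes["chrom"].astype(str).to_numpy()
            if "chrom" in genes.columns
            else np.full(len(gene_ids), "1")
        )
    else:
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        counts = df.to_numpy(dtype=float)
        gene_ids = df.index.astype(str)
        cell_ids = df.columns.astype(str)
        chrom = np.full(len(gene_ids), "1")

    if np.any(counts < 0):
        raise ValueError("negative counts in matrix")
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("non-integer counts in matrix")

    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    for col in META_COLUMNS:
        if col not in meta.columns:
            raise ValueError(f"metadata missing column '{col}'")
    missing = set(cell_ids) - set(meta.index)
    if missing:
        raise ValueError(f"cells absent from metadata: {sorted(missing)[:5]} ...")
    obs = meta.loc[list(cell_ids), list(META_COLUMNS)].copy()
    var = pd.DataFrame({"chrom": chrom}, index=pd.Index(gene_ids, name="gene_id"))
    return CountMatrix(counts=counts, obs=obs, var=var)


def write_counts(cm: CountMatrix, path: str, meta_path: str) -> None:
    """Write counts as MatrixMarket + sidecars (or dense CSV/TSV) + meta TSV."""
    if path.endswith(".mtx"):
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(cm.counts))
        stem = path[: -len(".mtx")]
        cm.var.to_csv(stem + "_genes.tsv", sep="\t", index_label="gene_id")
        pd.DataFrame(index=cm.obs.index).to_csv(
            stem + "_cells.tsv", sep="\t", index_label="cell_id"
        )
    else:
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
        pd.DataFrame(
            cm.counts.astype(int), index=cm.var.index, columns=cm.obs.index
        ).to_csv(path, sep=sep, index_label="gene_id")
    cm.obs.to_csv(meta_path, sep="\t", index_label="cell_id")


# --- GMT ----------------------------------------------------------------


def load_gmt(path: str) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            name = fields[0]
            seen: list[str] = []
            for g in fields[2:]:
                if g and g not in seen:
                    seen.append(g)
            sets[name] = seen
            desc[name] = fields[1]
    return GeneSetCollection(sets, desc)


def write_gmt(gsc: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in gsc.sets.items():
            d = gsc.descriptions.get(name, "na")
            fh.write("\t".join([name, d, *genes]) + "\n")


# --- MEME minimal motif format ------------------------------------------

_MEME_HEADER = "MEME version 4"


def load_pwms(path: str) -> list[PWM]:
    """Read PWMs from a MEME minimal motif file (probability matrices)."""
    pwms: list[PWM] = []
    name = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            m = re.match(r"^MOTIF\s+(\S+)", line)
            if m:
                if name is not None:
                    pwms.append(PWM(name, np.array(rows).T))
                name = m.group(1)
                rows = []
                continue
            if name is not None and re.match(r"^[0-9.eE+\-]+(\s+[0-9.eE+\-]+){3}$", line):
                rows.append([float(v) for v in line.split()])
    if name is not None:
        pwms.append(PWM(name, np.array(rows).T))
    if not pwms:
        raise ValueError(f"no motifs found in {path}")
    return pwms


def write_pwms(pwms: list[PWM], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_MEME_HEADER + "\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.length} "
                f"nsites= 20 E= 0\n"
            )
            for col in pwm.matrix.T:
                fh.write(" " + "  ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


# --- TSS ----------------------------------------------------------------


def load_tss(path: str) -> list[TSSRecord]:
    """Read TSS records from a TSV with columns chrom, pos, strand, gene_id."""
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "pos", "strand", "gene_id"):
        if col not in df.columns:
            raise ValueError(f"TSS file missing column '{col}'")
    return [
        TSSRecord(
            gene_id=str(r.gene_id), chrom=str(r.chrom), pos=int(r.pos), strand=str(r.strand)
        )
        for r in df.itertuples()
    ]


def write_tss(records: list[TSSRecord], path: str) -> None:
    pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "strand": [r.strand for r in records],
            "gene_id": [r.gene_id for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


# --- PPI ----------------------------------------------------------------


def load_ppi(path: str) -> PPIMatrix:
    """Read a 3-column TF / TF / score TSV; symmetrize by the max direction."""
    df = pd.read_csv(path, sep="\t", header=None, names=["a", "b", "score"], comment="#")
    if np.any((df["score"] < 0) | (df["score"] > 1)):
        raise ValueError("PPI scores must lie in [0, 1]")
    tfs = sorted(set(df["a"].astype(str)) | set(df["b"].astype(str)))
    idx = {t: i for i, t in enumerate(tfs)}
    mat = np.zeros((len(tfs), len(tfs)))
    for r in df.itertuples():
        i, j = idx[str(r.a)], idx[str(r.b)]
        mat[i, j] = max(mat[i, j], float(r.score))
    mat = np.maximum(mat, mat.T)
    np.fill_diagonal(mat, 1.0)
    return PPIMatrix(tf_ids=tfs, scores=mat)


def write_ppi(ppi: PPIMatrix, path: str) -> None:
    with open(path, "w") as fh:
        n = len(ppi.tf_ids)
        for i in range(n):
            for j in range(i + 1, n):
                fh.write(f"{ppi.tf_ids[i]}\t{ppi.tf_ids[j]}\t{ppi.scores[i, j]:.6f}\n")


# --- FASTA --------------------------------------------------------------


def read_fasta(path: str) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
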