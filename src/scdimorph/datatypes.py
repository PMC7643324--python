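"""Core in-memory containers shared by every pipeline stage.

Expression data are held gene x cell (genes are rows throughout, matching
the orientation of count-matrix deliveries from plate-based pipelines);
per-cell annotations (sex, cell type, batch) and per-gene annotations
(chromosome) travel with the matrix as pandas DataFrames indexed by id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_SEXES = ("F", "M")


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} ids")


@dataclass
class CountMatrix:
    """Gene x cell read counts with cell and gene metadata.

    counts : (n_genes, n_cells) non-negative array.  Integer-valued on load;
        imputation may introduce non-integer non-negative values.
    obs : per-cell DataFrame indexed by cell id with columns
        ``sex`` (in {F, M}), ``cell_type``, ``batch``.
    var : per-gene DataFrame indexed by gene id with column ``chrom``.
    """

    counts: np.ndarray
    obs: pd.DataFrame
    var: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-d (genes x cells)")
        if self.counts.shape != (len(self.var), len(self.obs)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.var)} genes x {len(self.obs)} cells"
            )
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite and non-negative")
        _check_unique(list(self.var.index), "gene")
        _check_unique(list(self.obs.index), "cell")
        for col in ("sex", "cell_type", "batch"):
            if col not in self.obs.columns:
                raise ValueError(f"cell metadata is missing column '{col}'")
        bad = set(self.obs["sex"]) - set(VALID_SEXES)
        if bad:
            raise ValueError(f"invalid sex labels: {sorted(bad)}")
        if "chrom" not in self.var.columns:
            raise ValueError("gene metadata is missing column 'chrom'")

    # convenience views -------------------------------------------------
    @property
    def gene_ids(self) -> np.ndarray:
        return self.var.index.to_numpy()

    @property
    def cell_ids(self) -> np.ndarray:
        return self.obs.index.to_numpy()

    @property
    def sex(self) -> np.ndarray:
        return self.obs["sex"].to_numpy()

    @property
    def cell_type(self) -> np.ndarray:
        return self.obs["cell_type"].to_numpy()

    @property
    def batch(self) -> np.ndarray:
        return self.obs["batch"].to_numpy()

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def require_integer(self) -> None:
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("counts must be integer-valued")

    def subset(self, genes=None, cells=None) -> "CountMatrix":
        """Return a copy restricted to boolean masks or id lists."""
        gsel = _as_indexer(genes, self.var.index)
        csel = _as_indexer(cells, self.obs.index)
        return CountMatrix(
            counts=self.counts[np.ix_(gsel, csel)].copy(),
            obs=self.obs.iloc[csel].copy(),
            var=self.var.iloc[gsel].copy(),
        )

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), self.obs.copy(), self.var.copy())


def _as_indexer(sel, index: pd.Index) -> np.ndarray:
    if sel is None:
        return np.arange(len(index))
    sel = np.asarray(sel)
    if sel.dtype == bool:
        if sel.size != len(index):
            raise ValueError("boolean mask length mismatch")
        return np.flatnonzero(sel)
    return index.get_indexer_for(list(sel))


@dataclass
class NormalizedMatrix:
    """Gene x cell log-normalized expression plus a provenance trail."""

    values: np.ndarray
    obs: pd.DataFrame
    var: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.var), len(self.obs)):
            raise ValueError("values shape does not match metadata")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("normalized values must be finite")

    @property
    def gene_ids(self) -> np.ndarray:
        return self.var.index.to_numpy()

    @property
    def cell_ids(self) -> np.ndarray:
        return self.obs.index.to_numpy()

    @property
    def sex(self) -> np.ndarray:
        return self.obs["sex"].to_numpy()

    def subset(self, genes=None, cells=None) -> "NormalizedMatrix":
        gsel = _as_indexer(genes, self.var.index)
        csel = _as_indexer(cells, self.obs.index)
        return NormalizedMatrix(
            values=self.values[np.ix_(gsel, csel)].copy(),
            obs=self.obs.iloc[csel].copy(),
            var=self.var.iloc[gsel].copy(),
            provenance=list(self.provenance),
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with optional descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set '{name}' is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set '{name}' has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, universe, min_size: int = 1) -> "GeneSetCollection":
        """Intersect every set with ``universe``; drop sets below ``min_size``."""
        uni = set(universe)
        kept = {}
        for name, genes in self.sets.items():
            inter = [g for g in genes if g in uni]
            if len(inter) >= min_size:
                kept[name] = inter
        return GeneSetCollection(
            kept, {k: v for k, v in self.descriptions.items() if k in kept}
        )


@dataclass
class PWM:
    """Position weight matrix: 4 x L base probabilities over (A, C, G, T)."""

    name: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValueError("PWM matrix must be 4 x L with L >= 1")
        if np.any(self.matrix < 0):
            raise ValueError("PWM probabilities must be non-negative")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(f"PWM '{self.name}' columns must sum to 1 (got {sums})")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))


@dataclass(frozen=True)
class TSSRecord:
    """One annotated transcription start site (1-based genomic coordinate)."""

    gene_id: str
    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("TSS position must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand '{self.strand}'")


@dataclass
class PPIMatrix:
    """Symmetric TF x TF interaction scores in [0, 1] with unit diagonal."""

    tf_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.tf_ids)
        _check_unique(self.tf_ids, "TF")
        if self.scores.shape != (n, n):
            raise ValueError("PPI score matrix shape mismatch")
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("PPI scores must lie in [0, 1]")
        if not np.allclose(self.scores, self.scores.T):
            raise ValueError("PPI matrix must be symmetric")
        if not np.allclose(np.diag(self.scores), 1.0):
            raise ValueError("PPI diagonal must be 1")
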