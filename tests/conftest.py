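import numpy as np
import pandas as pd
import pytest

from scdimorph.datatypes import CountMatrix, NormalizedMatrix


def make_count_matrix(counts, sex=None, cell_type=None, batch=None, chrom=None,
                      gene_ids=None, cell_ids=None) -> CountMatrix:
    counts = np.asarray(counts, dtype=float)
    n_g, n_c = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_g)]
    cell_ids = cell_ids or [f"c{i}" for i in range(n_c)]
    obs = pd.DataFrame(
        {
            "sex": sex if sex is not None else ["F", "M"] * (n_c // 2) + ["F"] * (n_c % 2),
            "cell_type": cell_type if cell_type is not None else ["t"] * n_c,
            "batch": batch if batch is not None else ["b"] * n_c,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    var = pd.DataFrame(
        {"chrom": chrom if chrom is not None else ["1"] * n_g},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return CountMatrix(counts, obs, var)


def make_normalized(values, **kw) -> NormalizedMatrix:
    cm = make_count_matrix(np.ones_like(np.asarray(values, dtype=float)), **kw)
    return NormalizedMatrix(np.asarray(values, dtype=float), cm.obs, cm.var)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
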