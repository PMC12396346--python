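import numpy as np
import pytest

from gliaquant.sc_state import ExpressionMatrix


def make_matrix(
    values,
    samples=None,
    platforms=None,
    malignant=None,
    unit="counts",
    gene_ids=None,
    cell_ids=None,
):
    """Small-matrix builder for toy tests."""
    values = np.asarray(values, dtype=float)
    ng, nc = values.shape
    gene_ids = gene_ids or [f"G{i}" for i in range(ng)]
    cell_ids = cell_ids or [f"C{j}" for j in range(nc)]
    samples = samples or ["S0"] * nc
    platforms = platforms or {s: "umi" for s in set(samples)}
    malignant = np.ones(nc, dtype=bool) if malignant is None else malignant
    return ExpressionMatrix(
        values=values,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        sample_of_cell=samples,
        platform_of_sample=platforms,
        malignant=malignant,
        unit=unit,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_lognorm():
    """A 30x24 random lognorm matrix over two samples."""
    g = np.random.default_rng(42)
    vals = np.log2(g.gamma(2.0, 50.0, size=(30, 24)) / 10 + 1)
    return make_matrix(
        vals,
        samples=["A"] * 12 + ["B"] * 12,
        platforms={"A": "umi", "B": "smartseq2"},
        unit="lognorm",
    )
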