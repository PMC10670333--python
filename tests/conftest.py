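import numpy as np
import pytest

from virotrans.datatypes import HOST, VIRUS, CountMatrix, GeneAnnotation


def make_matrix(counts, origins=None, gene_ids=None, sample_ids=None) -> CountMatrix:
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    if gene_ids is None:
        gene_ids = [f"G{i}" for i in range(n_genes)]
    if origins is None:
        origins = [HOST] * n_genes
    if sample_ids is None:
        sample_ids = [f"S{j}" for j in range(n_samples)]
    genes = [GeneAnnotation(g, o) for g, o in zip(gene_ids, origins)]
    return CountMatrix(genes=genes, samples=list(sample_ids), counts=counts)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_matrix(rng):
    return make_matrix(rng.integers(0, 500, size=(50, 6)))
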