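import numpy as np
import pytest

from origins import GeneExpressionMatrix, edges_from_pairs, toy_fixture


@pytest.fixture
def toy():
    """Frozen 5-gene x 4-cell matrix, 3-edge network, hand-computed scores."""
    return toy_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_instance(rng, n_genes=None, n_cells=None, density=0.3, sparse=False):
    """A random non-negative matrix plus a random edge list over its genes."""
    import scipy.sparse as sp

    n_genes = n_genes or int(rng.integers(3, 51))
    n_cells = n_cells or int(rng.integers(1, 21))
    values = rng.random((n_genes, n_cells)) * 5
    values[rng.random((n_genes, n_cells)) > 0.7] = 0.0
    genes = [f"G{i}" for i in range(n_genes)]
    pairs = [
        (genes[a], genes[b])
        for a in range(n_genes)
        for b in range(a + 1, n_genes)
        if rng.random() < density
    ]
    if not pairs:
        pairs = [(genes[0], genes[1])]
    matrix = GeneExpressionMatrix(
        values=sp.csr_matrix(values) if sparse else values,
        gene_ids=genes,
        cell_ids=[f"c{k}" for k in range(n_cells)],
        layer_tag="normalized",
    )
    return matrix, edges_from_pairs(pairs)


def dense_quadratic_oracle(matrix, edges, convention="edge_once"):
    """Brute-force P_k = sum_ij A_ij x_ik x_jk over a dense symmetric A."""
    genes = {g.upper(): i for i, g in enumerate(matrix.gene_ids)}
    n = matrix.n_genes
    A = np.zeros((n, n))
    for a, b in edges:
        if a in genes and b in genes:
            i, j = genes[a], genes[b]
            A[i, j] = 1.0
            A[j, i] = 1.0
    X = matrix.toarray()
    P = np.einsum("ij,ik,jk->k", A, X, X)
    if convention == "edge_once":
        P = P / 2.0
    return P
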