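import numpy as np
import pytest

from sbmmrf import AbundanceMatrix, Network


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_counts():
    counts = np.array([
        [2, 2, 0, 4],
        [1, 0, 3, 0],
        [5, 1, 1, 1],
    ])
    return AbundanceMatrix(counts, ["tA", "tB", "tC", "tD"], ["s1", "s2", "s3"])


@pytest.fixture
def counts_tsv(tmp_path, small_counts):
    path = tmp_path / "counts.tsv"
    small_counts.to_frame().to_csv(path, sep="\t")
    return path


def planted_network(rng, sizes, intra, inter):
    """Block-structured Bernoulli graph with explicit block probabilities."""
    z = np.repeat(np.arange(len(sizes)), sizes)
    p = z.size
    K = len(sizes)
    omega = np.full((K, K), inter, dtype=float)
    np.fill_diagonal(omega, intra)
    probs = omega[np.ix_(z, z)]
    upper = np.triu(rng.random((p, p)) < probs, k=1)
    A = (upper | upper.T).astype(np.int8)
    return Network(A, [f"t{i}" for i in range(p)]), z


@pytest.fixture
def two_cliques():
    """Two disjoint 10-cliques: the easiest possible 2-community graph."""
    A = np.zeros((20, 20), dtype=np.int8)
    A[:10, :10] = 1
    A[10:, 10:] = 1
    np.fill_diagonal(A, 0)
    z = np.repeat([0, 1], 10)
    return Network(A, [f"t{i}" for i in range(20)]), z
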