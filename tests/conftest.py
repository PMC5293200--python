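import numpy as np
import pytest

from unodf import BinaryNetwork, WeightedNetwork


def random_binary_network(
    n: int, density: float, directed: bool, seed: int
) -> BinaryNetwork:
    """Random test network of given size/density (not the null model)."""
    rng = np.random.default_rng(seed)
    if directed:
        A = (rng.random((n, n)) < density).astype(np.int8)
        np.fill_diagonal(A, 0)
    else:
        A = np.zeros((n, n), dtype=np.int8)
        iu, ju = np.triu_indices(n, k=1)
        A[iu, ju] = rng.random(iu.size) < density
        A += A.T
    return BinaryNetwork(A, directed=directed)


@pytest.fixture
def triangle_pendant() -> BinaryNetwork:
    """Triangle 1-2-3 with a pendant node 4 attached to node 1.

    This is also the perfectly nested network on 4 nodes: degrees
    (3, 2, 2, 1) and UNODF exactly 0.5.
    """
    A = np.array(
        [
            [0, 1, 1, 1],
            [1, 0, 1, 0],
            [1, 1, 0, 0],
            [1, 0, 0, 0],
        ],
        dtype=np.int8,
    )
    return BinaryNetwork(A)


@pytest.fixture
def small_weighted() -> WeightedNetwork:
    """N=3 symmetric weights w12=0.05, w13=0.4, w23=1.0 (standardized)."""
    W = np.array(
        [
            [0.0, 0.05, 0.4],
            [0.05, 0.0, 1.0],
            [0.4, 1.0, 0.0],
        ]
    )
    return WeightedNetwork(W, standardized=True)
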