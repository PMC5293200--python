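"""Synthetic one-mode network archetypes.

Four binary archetypes span the nestedness range at matched size and
connectance: a regular (checkerboard) graph where links are spread
evenly and nestedness is exactly zero, a modular graph of densely
linked blocks, an Erdős–Rényi random graph, and a perfectly nested
staircase where every lower-degree node's neighbourhood is contained in
every higher-degree node's. A preferential-attachment (Barabási–Albert)
generator provides heavy-tailed degree sequences, and ``attach_weights``
turns any binary archetype into a standardized weighted network so the
cut-off sweep can be exercised end to end.

The perfectly nested construction links nodes i and j (1-based) iff
i + j <= N + 1: the maximal staircase compatible with a symmetric
zero-diagonal matrix. Its UNODF grows with N and approaches (but never
reaches) 1, since the zero diagonal and at most one tied middle pair
always withhold a little overlap.
"""

from __future__ import annotations

from typing import Literal

import networkx as nx
import numpy as np

from .metric import BinaryNetwork, MIN_NODES
from .thresholds import WeightedNetwork, standardize_weights

__all__ = [
    "gen_perfectly_nested",
    "gen_regular",
    "gen_random",
    "gen_modular",
    "gen_preferential",
    "attach_weights",
]

WeightDistribution = Literal["uniform", "exponential", "constant"]


def gen_perfectly_nested(N: int) -> BinaryNetwork:
    """Staircase network: nodes i, j (1-based) linked iff i + j <= N + 1."""
    if N < MIN_NODES:
        raise ValueError(f"N must be >= {MIN_NODES}")
    i, j = np.indices((N, N))
    A = ((i + j + 2 <= N + 1) & (i != j)).astype(np.int8)
    return BinaryNetwork(A)


def gen_regular(N: int, k: int) -> BinaryNetwork:
    """Circulant k-regular graph (the checkerboard archetype)."""
    if N < MIN_NODES:
        raise ValueError(f"N must be >= {MIN_NODES}")
    if not 0 < k < N or k % 2 != 0:
        raise ValueError("k must be even with 0 < k < N")
    g = nx.circulant_graph(N, list(range(1, k // 2 + 1)))
    A = nx.to_numpy_array(g, nodelist=range(N), dtype=np.int8)
    return BinaryNetwork(A)


def gen_random(N: int, C: float, seed: int) -> BinaryNetwork:
    """Erdős–Rényi graph: each unordered pair linked with probability C."""
    if N < MIN_NODES:
        raise ValueError(f"N must be >= {MIN_NODES}")
    if not 0.0 < C < 1.0:
        raise ValueError("C must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(N, k=1)
    A = np.zeros((N, N), dtype=np.int8)
    A[iu, ju] = rng.random(iu.size) < C
    A += A.T
    return BinaryNetwork(A)


def gen_modular(
    N: int, n_blocks: int, p_in: float, p_out: float, seed: int
) -> BinaryNetwork:
    """Planted-partition graph: dense equal-sized blocks, sparse between.

    Remainder nodes join the last block.
    """
    if N < MIN_NODES:
        raise ValueError(f"N must be >= {MIN_NODES}")
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if N // n_blocks < 2:
        raise ValueError("blocks must have at least 2 nodes")
    if not p_in > p_out:
        raise ValueError("p_in must exceed p_out")
    size = N // n_blocks
    block = np.minimum(np.arange(N) // size, n_blocks - 1)
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(N, k=1)
    p = np.where(block[iu] == block[ju], p_in, p_out)
    A = np.zeros((N, N), dtype=np.int8)
    A[iu, ju] = rng.random(iu.size) < p
    A += A.T
    return BinaryNetwork(A)


def gen_preferential(N: int, m: int, seed: int) -> BinaryNetwork:
    """Barabási–Albert growth: new nodes attach to m degree-weighted targets."""
    if N < MIN_NODES:
        raise ValueError(f"N must be >= {MIN_NODES}")
    if not 1 <= m < N:
        raise ValueError("m must satisfy 1 <= m < N")
    g = nx.barabasi_albert_graph(N, m, seed=int(seed))
    A = nx.to_numpy_array(g, nodelist=range(N), dtype=np.int8)
    return BinaryNetwork(A)


def attach_weights(
    net: BinaryNetwork, distribution: WeightDistribution, seed: int = 0
) -> WeightedNetwork:
    """Give every link an independent positive weight, then standardize.

    ``uniform`` draws from (0, 1], ``exponential`` with unit mean,
    ``constant`` assigns 1 everywhere. Undirected networks get symmetric
    weights (one draw per unordered pair).
    """
    rng = np.random.default_rng(seed)
    A = net.adjacency
    n = net.n_nodes

    def draw(size: int) -> np.ndarray:
        if distribution == "uniform":
            return 1.0 - rng.random(size)  # (0, 1]
        if distribution == "exponential":
            return rng.exponential(1.0, size)
        if distribution == "constant":
            return np.ones(size)
        raise ValueError(f"unknown distribution {distribution!r}")

    W = np.zeros((n, n))
    if net.directed:
        idx = np.nonzero(A)
        W[idx] = draw(idx[0].size)
    else:
        iu, ju = np.triu_indices(n, k=1)
        present = A[iu, ju] > 0
        vals = np.zeros(iu.size)
        vals[present] = draw(int(present.sum()))
        W[iu, ju] = vals
        W += W.T
    wnet = WeightedNetwork(W, net.labels, net.directed)
    return standardize_weights(wnet)
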