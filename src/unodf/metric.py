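"""Nestedness of binary one-mode (unipartite) networks.

A one-mode network is a single set of N nodes any two of which may
interact, represented by a square adjacency matrix A with zero diagonal
(self-interactions are disregarded). Nestedness is the tendency of the
neighbourhoods of weakly connected nodes to be proper subsets of the
neighbourhoods of strongly connected ones.

UNODF (Unipartite Nestedness based on Overlap and Decreasing Fill)
averages, over all node pairs (i, j) with *unequal* degrees, the fraction
of the lower-degree node's links shared with the higher-degree node::

    UNODF = 2 / (N(N-1)) * sum_{i<j} (1 - delta_{ki,kj})
            * sum_{l != i,j} a_il a_jl / min(k_i, k_j)

Equal-degree pairs contribute zero ("decreasing fill": a set can only be
a proper subset of a strictly larger set) but remain in the N(N-1)/2
normalisation, so UNODF lies in [0, 1) — the zero diagonal keeps even a
perfectly nested matrix below 1. For an undirected (symmetric) matrix
the row-wise and column-wise values coincide; a directed network has two
values with different interpretations (in a food web with consumers in
rows, the row value measures resource-use overlap among consumers, the
column value how prey share consumers).

An earlier one-mode adaptation, here ``s_lee``, is identical except that
it keeps equal-degree pairs and sums the overlap over all l.

All public metric values are computed in exact rational arithmetic
(integer shared-link counts divided once at the end), so results are
bit-identical under any relabelling of the nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Orientation",
    "BinaryNetwork",
    "DegreeVector",
    "PairContribution",
    "UNODFResult",
    "degrees",
    "pair_contribution",
    "unodf",
    "unodf_reference",
    "s_lee",
]

logger = logging.getLogger("unodf")

Orientation = Literal["rows", "columns"]

MIN_NODES = 3  # the metric is degenerate below this size


def _default_labels(n: int) -> tuple[str, ...]:
    return tuple(f"n{i + 1}" for i in range(n))


@dataclass(frozen=True)
class BinaryNetwork:
    """Square 0/1 adjacency matrix with zero diagonal.

    Parameters
    ----------
    adjacency
        N x N array-like with entries in {0, 1} and zero diagonal.
    labels
        Unique node identifiers; defaults to ``n1 .. nN``.
    directed
        If False (default) the matrix must be exactly symmetric.
    """

    adjacency: np.ndarray
    labels: tuple[str, ...] = None  # type: ignore[assignment]
    directed: bool = False

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {A.shape}")
        n = A.shape[0]
        if n < MIN_NODES:
            raise ValueError(
                f"network must have at least {MIN_NODES} nodes, got {n}"
            )
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        A = A.astype(np.int8)
        if np.diagonal(A).any():
            raise ValueError("adjacency diagonal must be zero (no self-links)")
        if not self.directed and not np.array_equal(A, A.T):
            raise ValueError("undirected network requires a symmetric matrix")
        A.setflags(write=False)
        object.__setattr__(self, "adjacency", A)
        labels = self.labels
        if labels is None:
            labels = _default_labels(n)
        labels = tuple(str(x) for x in labels)
        if len(labels) != n:
            raise ValueError("labels length must match matrix size")
        if len(set(labels)) != n:
            raise ValueError("labels must be unique")
        object.__setattr__(self, "labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_links(self) -> int:
        """Number of links: unordered pairs if undirected, ordered if directed."""
        total = int(self.adjacency.sum())
        return total if self.directed else total // 2

    def transpose(self) -> "BinaryNetwork":
        return BinaryNetwork(self.adjacency.T.copy(), self.labels, self.directed)

    def permuted(self, order: Sequence[int]) -> "BinaryNetwork":
        """Simultaneous row/column permutation (relabelling of nodes)."""
        idx = np.asarray(order)
        return BinaryNetwork(
            self.adjacency[np.ix_(idx, idx)].copy(),
            tuple(self.labels[i] for i in idx),
            self.directed,
        )


@dataclass(frozen=True)
class DegreeVector:
    values: np.ndarray
    orientation: Orientation


@dataclass(frozen=True)
class PairContribution:
    """One summand of UNODF for a node pair (i < j)."""

    i: int
    j: int
    min_degree: int
    shared_count: int
    tied: bool
    value: Fraction


@dataclass(frozen=True)
class UNODFResult:
    unodf_rows: float
    unodf_cols: float
    n_pairs: int
    n_tied_rows: int
    n_tied_cols: int


def _oriented(net: BinaryNetwork, orientation: Orientation) -> np.ndarray:
    if orientation == "rows":
        return net.adjacency
    if orientation == "columns":
        return net.adjacency.T
    raise ValueError(f"orientation must be 'rows' or 'columns', got {orientation!r}")


def degrees(net: BinaryNetwork, orientation: Orientation = "rows") -> DegreeVector:
    """Row-sum (out-) or column-sum (in-) degrees of every node."""
    M = _oriented(net, orientation)
    return DegreeVector(M.sum(axis=1, dtype=np.int64), orientation)


def pair_contribution(
    net: BinaryNetwork, i: int, j: int, orientation: Orientation = "rows"
) -> PairContribution:
    """Nestedness contribution of the node pair (i, j).

    The shared count is the number of third nodes l (l != i, j) linked to
    both; the value is shared / min(k_i, k_j), zero for tied degrees or
    when the smaller degree is zero.
    """
    n = net.n_nodes
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"node indices ({i}, {j}) out of range for N={n}")
    if i == j:
        raise ValueError("pair requires two distinct nodes")
    if i > j:
        i, j = j, i
    M = _oriented(net, orientation)
    k = M.sum(axis=1, dtype=np.int64)
    mask = np.ones(n, dtype=bool)
    mask[[i, j]] = False
    shared = int((M[i] & M[j])[mask].sum())
    ki, kj = int(k[i]), int(k[j])
    tied = ki == kj
    m = min(ki, kj)
    if tied or m == 0:
        value = Fraction(0)
    else:
        value = Fraction(shared, m)
    return PairContribution(i, j, m, shared, tied, value)


def _unodf_oriented(M: np.ndarray) -> tuple[float, int]:
    """UNODF over the rows of ``M`` (pass the transpose for columns).

    Returns ``(value, n_tied_pairs)``. Integer shared counts are grouped
    by min-degree, summed exactly as rationals and converted to float
    once, making the result invariant under node relabelling.
    """
    M = M.astype(np.int64, copy=False)
    n = M.shape[0]
    k = M.sum(axis=1)
    shared = M @ M.T  # zero diagonal already excludes l = i and l = j
    iu, ju = np.triu_indices(n, k=1)
    ki, kj = k[iu], k[ju]
    tied = ki == kj
    m = np.minimum(ki, kj)
    ok = ~tied & (m > 0)
    num = np.bincount(m[ok], weights=shared[iu[ok], ju[ok]])
    total = sum(
        (Fraction(int(round(w)), int(d)) for d, w in enumerate(num) if w),
        Fraction(0),
    )
    value = float(2 * total / (n * (n - 1)))
    return value, int(tied.sum())


def unodf(net: BinaryNetwork) -> UNODFResult:
    """Compute UNODF across rows and across columns.

    For undirected networks the two orientations are identical and the
    column value is reused from the row computation.
    """
    rows_val, rows_tied = _unodf_oriented(net.adjacency)
    if net.directed:
        cols_val, cols_tied = _unodf_oriented(net.adjacency.T)
    else:
        cols_val, cols_tied = rows_val, rows_tied
    n = net.n_nodes
    return UNODFResult(rows_val, cols_val, n * (n - 1) // 2, rows_tied, cols_tied)


def unodf_reference(net: BinaryNetwork) -> UNODFResult:
    """Naive triple-loop UNODF, an independent oracle for testing.

    Evaluates the defining sum literally, pair by pair and third node by
    third node, with exact rational accumulation. Intended for small
    networks only (O(N^3) Python loops).
    """
    A = net.adjacency
    n = net.n_nodes
    out: dict[str, tuple[float, int]] = {}
    for orientation, M in (("rows", A), ("columns", A.T)):
        k = [int(sum(M[i, l] for l in range(n))) for i in range(n)]
        total = Fraction(0)
        tied = 0
        for i in range(n):
            for j in range(i + 1, n):
                if k[i] == k[j]:
                    tied += 1
                    continue
                m = min(k[i], k[j])
                if m == 0:
                    continue
                shared = sum(
                    int(M[i, l]) * int(M[j, l])
                    for l in range(n)
                    if l != i and l != j
                )
                total += Fraction(shared, m)
        out[orientation] = (float(2 * total / (n * (n - 1))), tied)
    return UNODFResult(
        out["rows"][0],
        out["columns"][0],
        n * (n - 1) // 2,
        out["rows"][1],
        out["columns"][1],
    )


def s_lee(net: BinaryNetwork, orientation: Orientation = "rows") -> float:
    """The earlier one-mode overlap metric S.

    Like UNODF but without the decreasing-fill condition: equal-degree
    pairs contribute their full overlap, and the third-node sum runs over
    all l (immaterial for zero-diagonal matrices). Pairs whose smaller
    degree is zero contribute 0.
    """
    M = _oriented(net, orientation).astype(np.int64, copy=False)
    n = M.shape[0]
    k = M.sum(axis=1)
    shared = M @ M.T
    iu, ju = np.triu_indices(n, k=1)
    m = np.minimum(k[iu], k[ju])
    ok = m > 0
    num = np.bincount(m[ok], weights=shared[iu[ok], ju[ok]])
    total = sum(
        (Fraction(int(round(w)), int(d)) for d, w in enumerate(num) if w),
        Fraction(0),
    )
    return float(2 * total / (n * (n - 1)))
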