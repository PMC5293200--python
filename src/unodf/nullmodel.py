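"""Degree-proportional null model and Monte-Carlo significance tests.

The benchmark ensemble keeps the empirical network size and expected
connectance while preserving degree heterogeneity without fixing any
individual degree: the probability of a link between two nodes is
proportional to the links each has in the observed network. For an
undirected network with degrees k_i,

    p_ij = (k_i + k_j) / (2 (N - 1)),   p_ii = 0,

so that sum_{i<j} p_ij equals the observed link count exactly and the
expected degree of node i is affine in k_i. For a directed network the
analogue p_ij = (k_i^out + k_j^in) / (2 (N - 1)) per ordered pair
preserves the expected totals the same way.

Significance follows the confidence-interval convention: the observed
UNODF is compared with the percentile interval of the null ensemble
(95% by default) and flagged significant when it falls outside. A
one-tailed upper p-value with the add-one correction,
p = (1 + #{null >= observed}) / (1 + replicates), is reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .metric import BinaryNetwork, _unodf_oriented

__all__ = [
    "NullModelConfig",
    "SignificanceResult",
    "link_probabilities",
    "sample_null",
    "null_distribution",
    "significance",
]

logger = logging.getLogger("unodf")


@dataclass(frozen=True)
class NullModelConfig:
    replicates: int = 1000
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass(frozen=True)
class SignificanceResult:
    empirical: float
    null_values: np.ndarray
    ci_low: float
    ci_high: float
    p_value: float
    significant: bool


def link_probabilities(net: BinaryNetwork) -> np.ndarray:
    """Per-pair link probabilities of the degree-proportional null model."""
    A = net.adjacency.astype(np.float64)
    n = net.n_nodes
    if net.directed:
        k_out = A.sum(axis=1)
        k_in = A.sum(axis=0)
        p = (k_out[:, None] + k_in[None, :]) / (2 * (n - 1))
    else:
        k = A.sum(axis=1)
        p = (k[:, None] + k[None, :]) / (2 * (n - 1))
    np.fill_diagonal(p, 0.0)
    return p


def sample_null(
    probs: np.ndarray, directed: bool, rng: np.random.Generator
) -> BinaryNetwork:
    """Draw one network with independent Bernoulli links from ``probs``."""
    A = _sample_batch(np.asarray(probs, dtype=np.float64), directed, rng, 1)[0]
    return BinaryNetwork(A, directed=directed)


def _sample_batch(
    probs: np.ndarray, directed: bool, rng: np.random.Generator, size: int
) -> np.ndarray:
    n = probs.shape[0]
    if directed:
        A = (rng.random((size, n, n)) < probs).astype(np.int8)
        A[:, np.arange(n), np.arange(n)] = 0
    else:
        iu, ju = np.triu_indices(n, k=1)
        hits = (rng.random((size, iu.size)) < probs[iu, ju]).astype(np.int8)
        A = np.zeros((size, n, n), dtype=np.int8)
        A[:, iu, ju] = hits
        A += A.transpose(0, 2, 1)
    return A


def _degenerate(A: np.ndarray, directed: bool) -> bool:
    """True when no unequal-positive-degree pair exists on any orientation."""
    for M in (A, A.T) if directed else (A,):
        k = M.sum(axis=1)
        pos = k[k > 0]
        if pos.size >= 3 and np.unique(pos).size >= 2:
            return False
    return True


def null_distribution(
    net: BinaryNetwork, config: NullModelConfig
) -> tuple[np.ndarray, np.ndarray]:
    """UNODF (rows, columns) for ``config.replicates`` null samples.

    Degenerate samples (too dismantled for any pair to contribute) are
    kept with their trivial UNODF of 0 rather than resampled, so the
    ensemble stays unbiased; their count is logged.
    """
    probs = link_probabilities(net)
    rng = np.random.default_rng(config.seed)
    batch = _sample_batch(probs, net.directed, rng, config.replicates)
    rows = np.empty(config.replicates)
    cols = np.empty(config.replicates)
    n_degenerate = 0
    for b, A in enumerate(batch):
        rows[b], _ = _unodf_oriented(A)
        cols[b] = _unodf_oriented(A.T)[0] if net.directed else rows[b]
        if _degenerate(A, net.directed):
            n_degenerate += 1
    if n_degenerate:
        logger.warning(
            "%d of %d null samples were degenerate (UNODF trivially 0)",
            n_degenerate,
            config.replicates,
        )
    return rows, cols


def significance(
    empirical: float, null_values: np.ndarray, ci_level: float = 0.95
) -> SignificanceResult:
    """Compare an observed value against a null ensemble.

    ``significant`` is two-sided (outside the percentile CI); the
    reported p-value is the one-tailed upper add-one estimate.
    """
    null_values = np.asarray(null_values, dtype=np.float64)
    if null_values.size == 0:
        raise ValueError("null_values must be non-empty")
    alpha = (1.0 - ci_level) / 2.0
    q = np.quantile(null_values, [alpha, 1.0 - alpha])
    ci_low, ci_high = float(q[0]), float(q[1])
    empirical = float(empirical)
    p = (1 + int((null_values >= empirical).sum())) / (1 + null_values.size)
    sig = empirical < ci_low or empirical > ci_high
    return SignificanceResult(empirical, null_values, ci_low, ci_high, p, sig)
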