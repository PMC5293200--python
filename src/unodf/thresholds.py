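"""Weight standardization and the cut-off binarization sweep.

Weighted one-mode networks are made comparable across systems by
dividing every link weight by the system's maximum weight, so weights
lie in [0, 1]. A binary network is then derived at each cut-off c in
{0.0, 0.1, ..., 0.9}: a link is present iff its standardized weight is
at least c (and strictly positive, so cut-off 0 keeps exactly the
recorded interactions). Sweeping the grid shows how robust nestedness is
to discarding weak links; at high cut-offs a network may dismantle to
the point where the metric carries no information, which is recorded
rather than silently reported as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .metric import BinaryNetwork, MIN_NODES, _default_labels, unodf
from .nullmodel import (
    NullModelConfig,
    SignificanceResult,
    _degenerate,
    null_distribution,
    significance,
)

__all__ = [
    "WeightedNetwork",
    "SweepRecord",
    "DEFAULT_CUTOFFS",
    "standardize_weights",
    "binarize",
    "sweep",
]

logger = logging.getLogger("unodf")

#: cut-off grid at 0.1 intervals; exact float literals i/10
DEFAULT_CUTOFFS: tuple[float, ...] = tuple(i / 10 for i in range(10))

# guards against float artifacts like 3*0.1 = 0.30000000000000004:
# a weight equal to the nominal cut-off is always kept
_CUTOFF_TOL = 1e-9


@dataclass(frozen=True)
class WeightedNetwork:
    """Square nonnegative weight matrix with zero diagonal."""

    weights: np.ndarray
    labels: tuple[str, ...] = None  # type: ignore[assignment]
    directed: bool = False
    standardized: bool = False

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=np.float64)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"weights must be square, got shape {W.shape}")
        n = W.shape[0]
        if n < MIN_NODES:
            raise ValueError(f"network must have at least {MIN_NODES} nodes")
        if (W < 0).any():
            raise ValueError("weights must be nonnegative")
        if np.diagonal(W).any():
            raise ValueError("weight diagonal must be zero (no self-links)")
        if not self.directed and not np.array_equal(W, W.T):
            raise ValueError("undirected network requires a symmetric matrix")
        if self.standardized and W.size and W.max() > 1.0:
            raise ValueError("standardized weights must lie in [0, 1]")
        W = W.copy()
        W.setflags(write=False)
        object.__setattr__(self, "weights", W)
        labels = self.labels
        if labels is None:
            labels = _default_labels(n)
        labels = tuple(str(x) for x in labels)
        if len(labels) != n or len(set(labels)) != n:
            raise ValueError("labels must be unique and match matrix size")
        object.__setattr__(self, "labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class SweepRecord:
    """Per-cutoff snapshot of the binarized network and its nestedness."""

    cutoff: float
    n_links: int
    connectance: float
    n_isolated: int
    unodf_rows: float | None
    unodf_cols: float | None
    significance_rows: SignificanceResult | None
    significance_cols: SignificanceResult | None
    dismantled: bool


def standardize_weights(wnet: WeightedNetwork) -> WeightedNetwork:
    """Divide all weights by the global maximum (idempotent)."""
    wmax = float(wnet.weights.max(initial=0.0))
    if wmax == 0.0:
        raise ValueError("cannot standardize an all-zero weight matrix")
    if wnet.standardized and wmax == 1.0:
        return wnet
    return WeightedNetwork(
        wnet.weights / wmax, wnet.labels, wnet.directed, standardized=True
    )


def binarize(wnet: WeightedNetwork, cutoff: float) -> BinaryNetwork:
    """Keep links with standardized weight >= cutoff (and > 0)."""
    if not wnet.standardized:
        raise ValueError("binarize requires a standardized network")
    if not 0.0 <= cutoff <= 0.9:
        raise ValueError(f"cutoff must lie in [0, 0.9], got {cutoff}")
    W = wnet.weights
    A = ((W >= cutoff - _CUTOFF_TOL) & (W > 0)).astype(np.int8)
    return BinaryNetwork(A, wnet.labels, wnet.directed)


def _connectance(net: BinaryNetwork) -> float:
    n = net.n_nodes
    possible = n * (n - 1) if net.directed else n * (n - 1) // 2
    return net.n_links / possible


def sweep(
    wnet: WeightedNetwork,
    cutoffs: Sequence[float] | None = None,
    null_config: NullModelConfig | None = None,
) -> list[SweepRecord]:
    """Binarize at each cut-off and measure UNODF (plus significance).

    Records come back in ascending cut-off order. Networks dismantled at
    a cut-off (no pair with unequal positive degrees on any orientation)
    carry no UNODF or significance values. Each cut-off gets its own
    reproducible null-model seed derived from ``null_config.seed``.
    """
    if not wnet.standardized:
        raise ValueError("sweep requires a standardized network")
    grid = sorted(DEFAULT_CUTOFFS if cutoffs is None else cutoffs)
    records: list[SweepRecord] = []
    for idx, cutoff in enumerate(grid):
        net = binarize(wnet, cutoff)
        A = net.adjacency
        linked = (A.sum(axis=1) + A.sum(axis=0)) > 0
        dismantled = _degenerate(A, net.directed)
        if dismantled:
            logger.warning("network dismantled at cutoff %.1f", cutoff)
            records.append(
                SweepRecord(
                    cutoff, net.n_links, _connectance(net),
                    int((~linked).sum()), None, None, None, None, True,
                )
            )
            continue
        res = unodf(net)
        sig_rows = sig_cols = None
        if null_config is not None:
            cfg = NullModelConfig(
                replicates=null_config.replicates,
                seed=int(
                    np.random.SeedSequence(
                        [null_config.seed, idx]
                    ).generate_state(1)[0]
                    & 0x7FFFFFFF
                ),
                ci_level=null_config.ci_level,
            )
            null_rows, null_cols = null_distribution(net, cfg)
            sig_rows = significance(res.unodf_rows, null_rows, cfg.ci_level)
            sig_cols = (
                sig_rows
                if not net.directed
                else significance(res.unodf_cols, null_cols, cfg.ci_level)
            )
        records.append(
            SweepRecord(
                cutoff,
                net.n_links,
                _connectance(net),
                int((~linked).sum()),
                res.unodf_rows,
                res.unodf_cols,
                sig_rows,
                sig_cols,
                False,
            )
        )
    return records
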