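"""Cross-network summaries: connectance, maximizing cut-off, correction.

UNODF rises with connectance (denser networks overlap more by chance
alone), so cross-system comparisons use two complements to the raw
value: the cut-off that maximizes UNODF in a sweep summarizes each
network at its most nested binarization, and residuals from an ordinary
least-squares fit of column-wise UNODF on connectance give a
connectance-corrected nestedness score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .metric import BinaryNetwork, Orientation
from .thresholds import SweepRecord

__all__ = [
    "NetworkSummary",
    "connectance",
    "select_max_cutoff",
    "connectance_correction",
    "summary_table",
]


@dataclass(frozen=True)
class NetworkSummary:
    name: str
    best_cutoff: float
    unodf_rows: float
    unodf_cols: float
    connectance: float
    p_value: float | None
    ci_low: float | None
    ci_high: float | None
    significant: bool | None
    corrected_unodf: float | None = None


def connectance(net: BinaryNetwork) -> float:
    """Realized fraction of possible links (diagonal excluded)."""
    n = net.n_nodes
    possible = n * (n - 1) if net.directed else n * (n - 1) // 2
    return net.n_links / possible


def _value(record: SweepRecord, orientation: Orientation) -> float:
    v = record.unodf_rows if orientation == "rows" else record.unodf_cols
    assert v is not None
    return v


def select_max_cutoff(
    records: Sequence[SweepRecord], orientation: Orientation = "columns"
) -> SweepRecord:
    """Record with maximal UNODF; ties go to the smallest cut-off."""
    valid = [r for r in records if not r.dismantled]
    if not valid:
        raise ValueError("all sweep records are dismantled")
    best = valid[0]
    for r in sorted(valid, key=lambda r: r.cutoff):
        if _value(r, orientation) > _value(best, orientation):
            best = r
    return best


def connectance_correction(
    points: Iterable[tuple[float, float]]
) -> np.ndarray:
    """OLS residuals of UNODF regressed on connectance.

    ``points`` are (unodf, connectance) pairs; residuals come back in
    input order and sum to zero (intercept included).
    """
    pts = np.asarray(list(points), dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (unodf, connectance) points")
    y, x = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("connectance values are all identical (degenerate fit)")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return np.asarray(fit.resid)


def _summarize(
    name: str, records: Sequence[SweepRecord], orientation: Orientation
) -> NetworkSummary:
    best = select_max_cutoff(records, orientation)
    sig = (
        best.significance_rows
        if orientation == "rows"
        else best.significance_cols
    )
    return NetworkSummary(
        name=name,
        best_cutoff=best.cutoff,
        unodf_rows=best.unodf_rows,  # type: ignore[arg-type]
        unodf_cols=best.unodf_cols,  # type: ignore[arg-type]
        connectance=best.connectance,
        p_value=sig.p_value if sig else None,
        ci_low=sig.ci_low if sig else None,
        ci_high=sig.ci_high if sig else None,
        significant=sig.significant if sig else None,
    )


def summary_table(
    sweeps: Mapping[str, Sequence[SweepRecord]],
    orientation: Orientation = "columns",
) -> pd.DataFrame:
    """One row per network at its maximizing cut-off.

    With three or more networks of distinct connectance, a
    ``corrected_unodf`` column holds the connectance-regression
    residuals (column-wise UNODF by convention).
    """
    summaries = [_summarize(nm, recs, orientation) for nm, recs in sweeps.items()]
    corrected: list[float | None] = [None] * len(summaries)
    conn = [s.connectance for s in summaries]
    if len(summaries) >= 3 and len(set(conn)) > 1:
        resid = connectance_correction(
            [(s.unodf_cols, s.connectance) for s in summaries]
        )
        corrected = list(resid)
    return pd.DataFrame(
        {
            "name": [s.name for s in summaries],
            "best_cutoff": [s.best_cutoff for s in summaries],
            "unodf_rows": [s.unodf_rows for s in summaries],
            "unodf_cols": [s.unodf_cols for s in summaries],
            "connectance": [s.connectance for s in summaries],
            "p_value": [s.p_value for s in summaries],
            "ci_low": [s.ci_low for s in summaries],
            "ci_high": [s.ci_high for s in summaries],
            "significant": [s.significant for s in summaries],
            "corrected_unodf": corrected,
        }
    )
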