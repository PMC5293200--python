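"""Reading and writing networks and results as delimited text.

Networks come in as square adjacency matrices (TSV/CSV, optionally with
matching row/column labels) or as 2–3 column edge lists. Self-links are
never retained: nonzero diagonal entries are zeroed with a warning and
self-loop edge-list rows are dropped, matching the metric's convention.
Results serialize as TSV or JSON with reals at 6 significant digits.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .analysis import NetworkSummary
from .thresholds import SweepRecord, WeightedNetwork

__all__ = [
    "MatrixFileSpec",
    "EdgeListSpec",
    "read_matrix",
    "read_edgelist",
    "write_matrix",
    "write_results",
]

logger = logging.getLogger("unodf")

_DELIMS = {"tab": "\t", "comma": ","}


@dataclass(frozen=True)
class MatrixFileSpec:
    path: str | Path
    delimiter: Literal["tab", "comma"] = "tab"
    has_labels: bool = True
    directed: bool = False


@dataclass(frozen=True)
class EdgeListSpec:
    path: str | Path
    delimiter: Literal["tab", "comma"] = "tab"
    directed: bool = False


def _finish_matrix(
    W: np.ndarray, labels: Sequence[str] | None, directed: bool
) -> WeightedNetwork:
    if (W < 0).any():
        raise ValueError("negative link weights are not allowed")
    if np.diagonal(W).any():
        logger.warning(
            "zeroing %d nonzero diagonal entries (self-interactions are "
            "disregarded)",
            int((np.diagonal(W) != 0).sum()),
        )
        W = W.copy()
        np.fill_diagonal(W, 0.0)
    if not directed and not np.array_equal(W, W.T):
        raise ValueError("matrix is asymmetric but directed=False")
    return WeightedNetwork(W, tuple(labels) if labels is not None else None, directed)


def read_matrix(spec: MatrixFileSpec) -> WeightedNetwork:
    """Load a square weighted adjacency matrix from delimited text."""
    sep = _DELIMS[spec.delimiter]
    if spec.has_labels:
        df = pd.read_csv(spec.path, sep=sep, header=0, index_col=0)
        labels = [str(c) for c in df.columns]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate node labels in matrix header")
        row_labels = [str(r) for r in df.index]
        if row_labels != labels:
            raise ValueError("row labels must match column labels in order")
    else:
        df = pd.read_csv(spec.path, sep=sep, header=None)
        labels = None
    W = df.to_numpy(dtype=np.float64)
    if W.shape[0] != W.shape[1]:
        raise ValueError(f"matrix is not square: shape {W.shape}")
    return _finish_matrix(W, labels, spec.directed)


def read_edgelist(spec: EdgeListSpec) -> WeightedNetwork:
    """Load a (source, target[, weight]) edge list into a dense matrix.

    Missing weight column means binary links (weight 1). Self-loops are
    dropped with a warning; conflicting duplicate weights are an error.
    """
    sep = _DELIMS[spec.delimiter]
    df = pd.read_csv(spec.path, sep=sep, header=None, comment="#")
    if df.shape[1] == 2:
        df[2] = 1.0
    elif df.shape[1] != 3:
        raise ValueError("edge list must have 2 or 3 columns")
    df.columns = ["source", "target", "weight"]
    df["source"] = df["source"].astype(str)
    df["target"] = df["target"].astype(str)
    df["weight"] = df["weight"].astype(np.float64)
    if (df["weight"] < 0).any():
        raise ValueError("negative link weights are not allowed")
    loops = df["source"] == df["target"]
    if loops.any():
        logger.warning("dropping %d self-loop edges", int(loops.sum()))
        df = df[~loops]
    labels = sorted(set(df["source"]) | set(df["target"]))
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    W = np.zeros((n, n))
    seen: dict[tuple[int, int], float] = {}
    for s, t, w in df.itertuples(index=False):
        i, j = index[s], index[t]
        key = (i, j) if spec.directed else (min(i, j), max(i, j))
        if key in seen and seen[key] != w:
            raise ValueError(f"conflicting duplicate weights for edge {s}-{t}")
        seen[key] = w
        W[i, j] = w
        if not spec.directed:
            W[j, i] = w
    return _finish_matrix(W, labels, spec.directed)


def write_matrix(
    wnet: WeightedNetwork,
    path: str | Path,
    delimiter: Literal["tab", "comma"] = "tab",
) -> None:
    """Write a labeled weight matrix as delimited text (round-trippable)."""
    sep = _DELIMS[delimiter]
    df = pd.DataFrame(wnet.weights, index=wnet.labels, columns=wnet.labels)
    df.to_csv(path, sep=sep, float_format="%.6g")


def _record_row(r: SweepRecord | NetworkSummary) -> dict:
    if isinstance(r, SweepRecord):
        return {
            "cutoff": r.cutoff,
            "n_links": r.n_links,
            "connectance": r.connectance,
            "n_isolated": r.n_isolated,
            "unodf_rows": r.unodf_rows,
            "unodf_cols": r.unodf_cols,
            "p_value_rows": r.significance_rows.p_value if r.significance_rows else None,
            "p_value_cols": r.significance_cols.p_value if r.significance_cols else None,
            "ci_low_rows": r.significance_rows.ci_low if r.significance_rows else None,
            "ci_high_rows": r.significance_rows.ci_high if r.significance_rows else None,
            "ci_low_cols": r.significance_cols.ci_low if r.significance_cols else None,
            "ci_high_cols": r.significance_cols.ci_high if r.significance_cols else None,
            "significant_rows": r.significance_rows.significant if r.significance_rows else None,
            "significant_cols": r.significance_cols.significant if r.significance_cols else None,
            "dismantled": r.dismantled,
        }
    return dataclasses.asdict(r)


def _round6(x):
    if isinstance(x, float):
        return float(f"{x:.6g}")
    return x


def write_results(
    records: Sequence[SweepRecord] | Sequence[NetworkSummary],
    path: str | Path,
    format: Literal["tsv", "json"] = "tsv",
    include_null: bool = False,
) -> None:
    """Serialize sweep records or network summaries.

    Column order is fixed; reals carry 6 significant digits. JSON output
    embeds full null-ensemble vectors only when ``include_null`` is set.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    rows = [_record_row(r) for r in records]
    if format == "tsv":
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
    elif format == "json":
        if include_null:
            for rec, row in zip(records, rows):
                if isinstance(rec, SweepRecord) and rec.significance_rows:
                    row["null_rows"] = [
                        _round6(v) for v in rec.significance_rows.null_values.tolist()
                    ]
                if (
                    isinstance(rec, SweepRecord)
                    and rec.significance_cols
                    and rec.significance_cols is not rec.significance_rows
                ):
                    row["null_cols"] = [
                        _round6(v) for v in rec.significance_cols.null_values.tolist()
                    ]
        rows = [{k: _round6(v) for k, v in row.items()} for row in rows]
        Path(path).write_text(json.dumps(rows, indent=2) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
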