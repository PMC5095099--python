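"""Readers and writers for the package's plain-text artifact formats.

Everything is tab-separated text or JSON: expression matrices (genes x
samples TSV, sample header row, gene-id first column), weight matrices (n x n
TSV with gene ids on both margins plus a JSON metadata sidecar), edge lists
(source/target/weight/ratio/sign/method TSV), stats bundles (JSON) and
optional GraphML for network viewers.  Floats are written with ``repr``
shortest-round-trip formatting, so write-then-read is exact and identical
runs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd

from .bp import TrainingConfig, WeightMatrix
from .errors import ParseError
from .matrix import ExpressionMatrix
from .network import Edge, RegulatoryNetwork
from .stats import NetworkStats

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_weight_matrix_tsv",
    "write_weight_matrix_tsv",
    "write_weight_metadata_json",
    "read_edge_list_tsv",
    "write_edge_list_tsv",
    "write_stats_json",
    "write_graphml",
    "write_json",
]

PathLike = Union[str, Path]


def _float_fmt(v) -> str:
    """Shortest exact-round-trip decimal representation."""
    return repr(float(v))


def _read_table(path: PathLike, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{what} file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # ragged rows, empty file, ...
        raise ParseError(f"could not parse {what} file {path}: {exc}") from exc
    return df


def _to_numeric(df: pd.DataFrame, path: PathLike, what: str) -> pd.DataFrame:
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        row_pos, col_pos = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric value {df.iat[row_pos, col_pos]!r} in {what} file "
            f"{path} at row {df.index[row_pos]!r}, column "
            f"{df.columns[col_pos]!r}"
        )
    if numeric.isna().to_numpy().any():
        row_pos, col_pos = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(
            f"missing value in {what} file {path} at row "
            f"{df.index[row_pos]!r}, column {df.columns[col_pos]!r}"
        )
    # to_numeric's fast parser is not correctly rounded; re-parse the
    # validated strings with numpy for an exact round trip
    return pd.DataFrame(df.to_numpy(dtype=np.float64), index=df.index,
                        columns=df.columns)


def read_expression_tsv(path: PathLike, group: Optional[str] = None
                        ) -> ExpressionMatrix:
    """Read a genes x samples expression TSV.

    First row: sample ids; first column: gene ids.  Duplicate ids, ragged
    rows and non-numeric cells raise :class:`~bpgrn.errors.ParseError`
    naming the offending gene/sample.
    """
    df = _read_table(path, "expression")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicate gene id {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ParseError(f"duplicate sample id {dup!r} in {path}")
    numeric = _to_numeric(df, path, "expression")
    return ExpressionMatrix.from_frame(numeric, group=group)


def write_expression_tsv(matrix: ExpressionMatrix, path: PathLike) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene",
                         float_format=_float_fmt)


def read_weight_matrix_tsv(path: PathLike) -> WeightMatrix:
    """Read an n x n weight matrix TSV (gene ids on both margins)."""
    df = _read_table(path, "weight matrix")
    numeric = _to_numeric(df, path, "weight matrix")
    if list(numeric.index) != list(numeric.columns):
        raise ParseError(f"weight matrix {path} row/column gene ids differ")
    return WeightMatrix(gene_ids=list(map(str, numeric.index)),
                        W=numeric.to_numpy(dtype=np.float64))


def write_weight_matrix_tsv(wm: WeightMatrix, path: PathLike) -> None:
    wm.to_frame().to_csv(path, sep="\t", index_label="gene",
                     float_format=_float_fmt)


def write_weight_metadata_json(wm: WeightMatrix, path: PathLike) -> None:
    """Config echo plus per-gene final error / convergence / cycle counts."""
    meta = {
        "config": dataclasses.asdict(wm.config) if wm.config else None,
        "genes": wm.gene_ids,
        "final_errors": None if wm.final_errors is None
        else [float(e) for e in wm.final_errors],
        "converged": None if wm.converged is None
        else [bool(c) for c in wm.converged],
        "cycles_run": None if wm.cycles_run is None
        else [int(c) for c in wm.cycles_run],
        "n_converged": None if wm.converged is None
        else int(np.sum(wm.converged)),
    }
    write_json(meta, path)


def write_edge_list_tsv(net: RegulatoryNetwork, path: PathLike) -> None:
    """Edge list with columns source, target, weight, ratio, sign, method."""
    rows = [
        {"source": e.source, "target": e.target, "weight": e.weight,
         "ratio": e.ratio, "sign": e.sign, "method": net.method}
        for e in net.edges
    ]
    df = pd.DataFrame(rows, columns=["source", "target", "weight", "ratio",
                                     "sign", "method"])
    df.to_csv(path, sep="\t", index=False, float_format=_float_fmt)


def read_edge_list_tsv(path: PathLike, gene_ids: Sequence[str],
                       threshold: float, method: str = "bp"
                       ) -> RegulatoryNetwork:
    """Rebuild a network from an edge-list TSV plus the gene universe
    (needed because isolated genes do not appear in the edge list)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"edge list file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    edges = [
        Edge(source=r.source, target=r.target, weight=float(r.weight),
             ratio=float(r.ratio), sign=str(r.sign))
        for r in df.itertuples(index=False)
    ]
    if len(df) and "method" in df.columns:
        method = str(df["method"].iloc[0])
    return RegulatoryNetwork(gene_ids=list(gene_ids), edges=edges,
                             threshold_used=float(threshold), method=method)


def write_stats_json(stats: Union[NetworkStats, Sequence[NetworkStats]],
                     path: PathLike, method: str = "bp") -> None:
    if isinstance(stats, NetworkStats):
        payload = {**stats.as_dict(), "method": method}
    else:
        payload = [{**s.as_dict(), "method": method} for s in stats]
    write_json(payload, path)


def write_graphml(net: RegulatoryNetwork, path: PathLike) -> None:
    """GraphML export of the directed network with edge attributes."""
    nx.write_graphml(net.to_directed(), str(path))


def write_json(payload, path: PathLike) -> None:
    """Deterministically formatted JSON (sorted keys, fixed separators)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
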