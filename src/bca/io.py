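"""Readers and writers for activity matrices and microcircuit graphs.

Activity matrices travel as plain CSV (comma separator, mandatory
header row of node labels, one sample per row).  Graphs travel as
two-column tab-separated edge lists preceded by a node-manifest header
block (``# node<TAB>label`` lines) so that isolated nodes survive a
round trip; edges are written as sorted label pairs, one per line.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .graphical_models import DataMatrix, Microcircuit

__all__ = [
    "read_data_csv",
    "write_data_csv",
    "read_graph",
    "write_graph",
    "write_adjacency_csv",
]


def read_data_csv(path, mode: str | None = None) -> DataMatrix:
    """Read an activity matrix from CSV (header row = node labels).

    Mode is auto-detected (all values in {0, 1} -> binary) unless
    ``mode`` overrides it.  Ragged rows, non-numeric cells and duplicate
    labels raise with the offending line number.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        labels = [h.strip() for h in header]
        if len(set(labels)) != len(labels):
            raise ValueError(f"{path}:1: duplicate node labels in header")
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(labels):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(labels)} fields, "
                    f"got {len(row)}")
            try:
                rows.append([float(c) for c in row])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric cell") from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return DataMatrix.from_array(np.asarray(rows), node_labels=labels, mode=mode)


def write_data_csv(path, data: DataMatrix) -> None:
    fmt = "%.0f" if data.mode == "binary" else "%.10g"
    df = pd.DataFrame(data.values, columns=list(data.node_labels))
    df.to_csv(path, index=False, float_format=fmt)


def write_graph(path, g: Microcircuit) -> None:
    """Write a graph as a node manifest plus a sorted edge list."""
    for label in g.node_labels:
        if "\t" in label or "\n" in label:
            raise ValueError(f"label {label!r} contains a tab or newline")
    path = Path(path)
    with path.open("w") as fh:
        for label in g.node_labels:
            fh.write(f"# node\t{label}\n")
        for a, b in sorted(g.edges()):
            fh.write(f"{a}\t{b}\n")


def read_graph(path) -> Microcircuit:
    """Read a graph written by :func:`write_graph`.

    Duplicate edge lines collapse to one edge; an edge referring to a
    label missing from the manifest is an error.
    """
    path = Path(path)
    labels: list[str] = []
    edges: set[tuple[str, str]] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("# node\t"):
                labels.append(line.split("\t", 1)[1])
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two fields")
            a, b = parts
            if a not in labels or b not in labels:
                raise ValueError(f"{path}:{lineno}: unknown label in edge "
                                 f"{a!r} - {b!r}")
            edges.add((a, b) if a <= b else (b, a))
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate labels in node manifest")
    return Microcircuit.from_edges(tuple(labels), edges)


def write_adjacency_csv(path, g: Microcircuit) -> None:
    """Adjacency matrix as CSV with a label header row and column."""
    df = pd.DataFrame(g.adjacency.astype(int),
                      index=list(g.node_labels), columns=list(g.node_labels))
    df.to_csv(path)
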