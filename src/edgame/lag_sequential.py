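"""Lag sequential analysis of coded behavior sequences.

Counts lag-k (default lag-1) transitions within each player's sequence,
pools them into one matrix, and tests each cell with the adjusted-residual
z statistic

    Z[i][j] = (O[i][j] - E[i][j]) / sqrt(E[i][j] * (1 - r_i/N) * (1 - c_j/N))

where E[i][j] = r_i * c_j / N with r, c the row/column marginals. Cells with
zero expected count or zero variance are undefined and never become edges.
Edges with z above the threshold (one-sided by default, matching transition
graphs that display excitatory links only) form a directed graph.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .behavior_coding import CodedSequence

__all__ = [
    "TransitionCountMatrix",
    "LSAResult",
    "count_transitions",
    "z_scores",
    "significant_edges",
    "write_z_matrix",
    "write_edge_list",
    "write_dot",
    "LSAError",
]


class LSAError(ValueError):
    pass


@dataclass(frozen=True)
class TransitionCountMatrix:
    codes: tuple[str, ...]
    observed: np.ndarray  # square, counts

    def __post_init__(self) -> None:
        o = np.asarray(self.observed)
        if o.shape != (len(self.codes), len(self.codes)):
            raise LSAError("observed matrix shape must match the code alphabet")
        if (o < 0).any():
            raise LSAError("transition counts must be non-negative")

    @property
    def n_transitions(self) -> int:
        return int(self.observed.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.observed.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.observed.sum(axis=0)


@dataclass(frozen=True)
class LSAResult:
    codes: tuple[str, ...]
    observed: np.ndarray
    expected: np.ndarray
    z: np.ndarray  # NaN where undefined
    threshold: float = 1.96

    def edge_list(self, threshold: float | None = None, two_sided: bool = False) -> list[tuple[str, str, float]]:
        thr = self.threshold if threshold is None else threshold
        edges = []
        for i, src in enumerate(self.codes):
            for j, dst in enumerate(self.codes):
                z = self.z[i, j]
                if np.isnan(z):
                    continue
                if (abs(z) if two_sided else z) > thr:
                    edges.append((src, dst, float(z)))
        return edges


def count_transitions(
    sequences: Sequence[CodedSequence],
    lag: int = 1,
    codes: Sequence[str] | None = None,
) -> TransitionCountMatrix:
    """Pool lag-``lag`` transition counts over sequences.

    Transitions are counted within each sequence only — never across
    players — so the pooled matrix is invariant to the order of sequences.
    """
    if lag < 1:
        raise LSAError("lag must be >= 1")
    if codes is None:
        alphabet = sorted({c for s in sequences for c in s.codes})
    else:
        alphabet = list(codes)
    index = {c: i for i, c in enumerate(alphabet)}
    O = np.zeros((len(alphabet), len(alphabet)), dtype=np.int64)
    for s in sequences:
        cs = s.codes
        if len(cs) <= lag:
            if cs:
                warnings.warn(
                    f"sequence {s.player_id!r} shorter than lag+1; contributes no transitions",
                    stacklevel=2,
                )
            continue
        for a, b in zip(cs[:-lag], cs[lag:]):
            O[index[a], index[b]] += 1
    return TransitionCountMatrix(tuple(alphabet), O)


def z_scores(counts: TransitionCountMatrix, threshold: float = 1.96) -> LSAResult:
    """Adjusted-residual z statistics for every transition cell."""
    N = counts.n_transitions
    if N < 2:
        raise LSAError(f"need at least 2 transitions, got {N}")
    O = counts.observed.astype(float)
    r = counts.row_totals.astype(float)
    c = counts.col_totals.astype(float)
    E = np.outer(r, c) / N
    var = E * (1.0 - r[:, None] / N) * (1.0 - c[None, :] / N)
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = (O - E) / np.sqrt(var)
    Z = np.where(var > 0, Z, np.nan)
    return LSAResult(counts.codes, counts.observed.copy(), E, Z, threshold)


def significant_edges(
    result: LSAResult,
    threshold: float = 1.96,
    two_sided: bool = False,
) -> nx.DiGraph:
    """Directed graph of significant transitions, deterministically ordered."""
    g = nx.DiGraph()
    g.add_nodes_from(result.codes)
    for src, dst, z in result.edge_list(threshold, two_sided):
        g.add_edge(src, dst, z=z)
    return g


def write_z_matrix(result: LSAResult, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["code", *result.codes])
        for i, src in enumerate(result.codes):
            w.writerow([src, *("" if np.isnan(z) else f"{z:.6g}" for z in result.z[i])])


def write_edge_list(edges: Sequence[tuple[str, str, float]], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "target", "z"])
        for src, dst, z in edges:
            w.writerow([src, dst, f"{z:.6g}"])


def write_dot(graph: nx.DiGraph, path: str | Path) -> None:
    """Minimal DOT export (no pydot dependency)."""
    lines = ["digraph transitions {"]
    for node in sorted(graph.nodes):
        lines.append(f'    "{node}";')
    for src, dst in sorted(graph.edges):
        z = graph.edges[src, dst]["z"]
        lines.append(f'    "{src}" -> "{dst}" [label="{z:.2f}"];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
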