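"""Per-edge substitution tabulation from an ancestral assignment.

The central object is a binary (edge × column) indicator matrix: 1 iff
the ancestral and descendant states on that edge differ and both are
standard residues. Transitions touching the missing symbol or a gap are
not substitutions. Marginal sums give per-edge totals (ranked with
terminal edges excluded by default) and per-column change counts, whose
grand totals must agree (the double-counting identity, asserted on every
build).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import AA_ALPHABET
from .trees import AncestralAssignment, TreeError

__all__ = [
    "EdgeSubstitutionTable",
    "EdgeReport",
    "build_edge_table",
    "edge_totals",
    "position_change_counts",
    "focal_edge_report",
    "position_character_sets",
    "write_edge_table_tsv",
    "write_edge_table_triples",
    "write_edge_report_tsv",
]

Edge = tuple[str, str]


@dataclass
class EdgeSubstitutionTable:
    edges: list[Edge]  # preorder over child nodes
    indicator: np.ndarray  # (n_edges, ncol) uint8
    is_terminal: np.ndarray  # (n_edges,) bool — edge leads to a leaf

    def __post_init__(self) -> None:
        assert self.indicator.shape[0] == len(self.edges)
        # double-counting identity: both marginals sum the same events
        assert int(self.indicator.sum(axis=1).sum()) == int(
            self.indicator.sum(axis=0).sum()
        )

    @property
    def ncol(self) -> int:
        return self.indicator.shape[1]

    def edge_index(self, edge: Edge) -> int:
        try:
            return self.edges.index(edge)
        except ValueError:
            raise KeyError(f"no edge {edge}") from None


@dataclass
class EdgeReport:
    """Substituted columns on one edge, with ancestral/descendant states."""

    edge: Edge
    entries: list[tuple[int, str, str]]  # (column, ancestral, descendant)
    reference_positions: list[int | None] | None = field(default=None)

    def __len__(self) -> int:
        return len(self.entries)


def build_edge_table(
    assignment: AncestralAssignment, alphabet: str = AA_ALPHABET
) -> EdgeSubstitutionTable:
    """Binary indicator per (edge, column): parent state != child state,
    both states standard residues."""
    tree = assignment.tree
    ncol = assignment.ncol
    valid = frozenset(alphabet)

    def encode(label: str) -> tuple[np.ndarray, np.ndarray]:
        seq = assignment.states[label]
        arr = np.frombuffer(seq.encode(), dtype="S1")
        ok = np.fromiter((c in valid for c in seq), count=ncol, dtype=bool)
        return arr, ok

    cache = {n.label: encode(n.label) for n in tree.preorder()}
    edges: list[Edge] = []
    rows = []
    terminal = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        p_arr, p_ok = cache[node.parent.label]
        c_arr, c_ok = cache[node.label]
        rows.append(((p_arr != c_arr) & p_ok & c_ok).astype(np.uint8))
        edges.append((node.parent.label, node.label))
        terminal.append(node.is_leaf)
    return EdgeSubstitutionTable(
        edges=edges,
        indicator=np.vstack(rows),
        is_terminal=np.asarray(terminal, dtype=bool),
    )


def edge_totals(
    table: EdgeSubstitutionTable, include_terminal: bool = False
) -> list[tuple[Edge, int]]:
    """Per-edge substitution totals, sorted descending (ties broken by edge
    label). Terminal edges are excluded from the ranking by default."""
    sums = table.indicator.sum(axis=1)
    items = [
        (edge, int(total))
        for edge, total, term in zip(table.edges, sums, table.is_terminal)
        if include_terminal or not term
    ]
    return sorted(items, key=lambda item: (-item[1], item[0]))


def position_change_counts(table: EdgeSubstitutionTable) -> np.ndarray:
    """Number of edges on which each 1-based column changed; index c-1."""
    return table.indicator.sum(axis=0).astype(np.int64)


def focal_edge_report(
    assignment: AncestralAssignment,
    table: EdgeSubstitutionTable,
    focal_child: str,
) -> EdgeReport:
    """All substituted columns on the edge above *focal_child*, with the
    ancestral and descendant states."""
    node = assignment.tree.find(focal_child)
    if node.parent is None:
        raise TreeError(f"{focal_child!r} is the root; it has no incoming edge")
    edge = (node.parent.label, node.label)
    row = table.indicator[table.edge_index(edge)]
    entries = [
        (col, assignment.state(edge[0], col), assignment.state(edge[1], col))
        for col in (np.flatnonzero(row) + 1).tolist()
    ]
    return EdgeReport(edge=edge, entries=entries)


def position_character_sets(
    assignment: AncestralAssignment,
    columns: list[int],
    alphabet: str = AA_ALPHABET,
) -> dict[int, set[str]]:
    """Per column, the union of non-missing states over every node (leaves
    and internals)."""
    valid = frozenset(alphabet)
    out: dict[int, set[str]] = {}
    for col in columns:
        if not 1 <= col <= assignment.ncol:
            raise IndexError(f"column {col} out of range 1..{assignment.ncol}")
        chars = {
            assignment.states[n.label][col - 1] for n in assignment.tree.preorder()
        }
        out[col] = chars & valid
    return out


def write_edge_table_tsv(table: EdgeSubstitutionTable, path) -> None:
    """Dense TSV: rows = edges, columns = alignment positions, cells 0/1."""
    with open(path, "w") as fh:
        fh.write("parent\tchild\t" + "\t".join(str(c) for c in range(1, table.ncol + 1)) + "\n")
        for (parent, child), row in zip(table.edges, table.indicator):
            fh.write(f"{parent}\t{child}\t" + "\t".join(map(str, row.tolist())) + "\n")


def write_edge_table_triples(table: EdgeSubstitutionTable, path) -> None:
    """Sparse TSV of the indicator-1 cells: (parent, child, column)."""
    with open(path, "w") as fh:
        fh.write("parent\tchild\tcolumn\n")
        for (parent, child), row in zip(table.edges, table.indicator):
            for col in (np.flatnonzero(row) + 1).tolist():
                fh.write(f"{parent}\t{child}\t{col}\n")


def write_edge_report_tsv(report: EdgeReport, path) -> None:
    refs = report.reference_positions or [None] * len(report.entries)
    with open(path, "w") as fh:
        fh.write("column\treference_position\tancestral\tdescendant\n")
        for (col, anc, desc), ref in zip(report.entries, refs):
            ref_str = "unmapped" if ref is None else str(ref)
            fh.write(f"{col}\t{ref_str}\t{anc}\t{desc}\n")
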