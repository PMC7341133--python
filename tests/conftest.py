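"""Shared fixtures and independent oracles.

The brute-force parsimony oracle enumerates every assignment of internal
states and is deliberately independent of the dynamic program it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mitoscan.seqio import MultipleAlignment, SequenceRecord
from mitoscan.trees import RootedTree, TreeNode


def brute_force_parsimony(tree: RootedTree, leaf_states: dict[str, str],
                          alphabet: str) -> int:
    """Minimum substitution count over all internal-state assignments.

    Edges touching a state outside *alphabet* (missing data) cost 0.
    """
    internals = tree.internals()
    edges = tree.edges()
    best = None
    for combo in itertools.product(alphabet, repeat=len(internals)):
        states = {n.label: s for n, s in zip(internals, combo)}
        states.update(leaf_states)
        cost = sum(
            1
            for p, c in edges
            if states[p] in alphabet and states[c] in alphabet and states[p] != states[c]
        )
        if best is None or cost < best:
            best = cost
    return best


def random_topology(n_leaves: int, rng: np.random.Generator,
                    multifurcate: bool = False) -> RootedTree:
    """Random rooted tree with leaves t1..tn (binary unless multifurcate)."""
    nodes = [TreeNode(f"t{i}") for i in range(1, n_leaves + 1)]
    while len(nodes) > 1:
        k = 2
        if multifurcate and len(nodes) > 2 and rng.random() < 0.4:
            k = 3
        picks = sorted(rng.choice(len(nodes), size=k, replace=False).tolist(),
                       reverse=True)
        parent = TreeNode()
        for i in picks:
            parent.add(nodes.pop(i))
        nodes.append(parent)
    return RootedTree(nodes[0])


def alignment_from_columns(tree: RootedTree, columns: list[str]) -> MultipleAlignment:
    """Build an alignment whose rows are the tree's leaves; columns[i] gives
    one character per leaf, in leaf-label order."""
    leaves = tree.leaf_labels()
    rows = {leaf: "".join(col[i] for col in columns) for i, leaf in enumerate(leaves)}
    return MultipleAlignment([SequenceRecord(l, s) for l, s in rows.items()])


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)
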