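"""Rooted phylogenies, Newick I/O, outgroup rooting, and parsimony
ancestral reconstruction.

Newick parsing is delegated to dendropy; the tree structure used by the
rest of the pipeline is a small dedicated class so that edges, labels and
traversal orders are fully deterministic.

Reconstruction uses small parsimony generalized to multifurcations
(Hartigan's vote-counting formulation, which reduces to Fitch
intersection/union on binary trees), with a deterministic top-down
resolution: inherit the parent state when possible, otherwise take the
alphabetically smallest candidate. Gaps and ambiguous residues at leaves
are uninformative; subtrees that are entirely missing in a column are
assigned the missing symbol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import dendropy
import numpy as np

from .seqio import AA_ALPHABET, MISSING, MultipleAlignment

__all__ = [
    "TreeError",
    "TreeNode",
    "RootedTree",
    "read_newick",
    "parse_newick",
    "root_on_edge",
    "AncestralAssignment",
    "reconstruct",
    "write_assignment_tsv",
    "write_ancestral_fasta",
]


class TreeError(ValueError):
    """Raised on malformed trees or invalid tree operations."""


class TreeNode:
    __slots__ = ("label", "children", "parent", "length")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {self.label!r} {kind}>"


class RootedTree:
    """A rooted tree with uniquely labeled nodes.

    Leaves carry sequence-record ids; internal nodes without input labels
    receive synthetic labels N1, N2, ... in preorder.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._label_unlabeled()
        self._check_labels()

    # -- construction helpers ------------------------------------------------

    def _label_unlabeled(self) -> None:
        taken = {n.label for n in self.preorder() if n.label}
        counter = 1
        for node in self.preorder():
            if not node.label:
                while f"N{counter}" in taken:
                    counter += 1
                node.label = f"N{counter}"
                taken.add(node.label)
                counter += 1

    def _check_labels(self) -> None:
        leaf_labels = [n.label for n in self.leaves()]
        if len(set(leaf_labels)) != len(leaf_labels):
            dup = sorted({x for x in leaf_labels if leaf_labels.count(x) > 1})
            raise TreeError(f"duplicate leaf label(s): {', '.join(dup)}")
        all_labels = [n.label for n in self.preorder()]
        if len(set(all_labels)) != len(all_labels):
            dup = sorted({x for x in all_labels if all_labels.count(x) > 1})
            raise TreeError(f"duplicate node label(s): {', '.join(dup)}")
        self._index = {n.label: n for n in self.preorder()}

    # -- traversal -----------------------------------------------------------

    def preorder(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def postorder(self) -> list[TreeNode]:
        return list(reversed([n for n in self._preorder_rightfirst()]))

    def _preorder_rightfirst(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def internals(self) -> list[TreeNode]:
        return [n for n in self.preorder() if not n.is_leaf]

    def edges(self) -> list[tuple[str, str]]:
        """All (parent label, child label) pairs, child in preorder."""
        return [(n.parent.label, n.label) for n in self.preorder() if n.parent]

    def find(self, label: str) -> TreeNode:
        try:
            return self._index[label]
        except KeyError:
            raise TreeError(f"no node labeled {label!r} in tree") from None

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def mrca(self, labels: Iterable[str]) -> TreeNode:
        """Most recent common ancestor of the named nodes."""
        labels = list(labels)
        if not labels:
            raise TreeError("mrca of an empty label set")
        paths = []
        for label in labels:
            node = self.find(label)
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(path[::-1])  # root ... node
        anc = None
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                anc = level[0]
            else:
                break
        assert anc is not None  # root is always shared
        return anc

    def clade_leaf_labels(self, label: str) -> frozenset[str]:
        node = self.find(label)
        out, stack = [], [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.label)
            stack.extend(n.children)
        return frozenset(out)

    # -- copy / serialize ----------------------------------------------------

    def copy(self) -> "RootedTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length)
            for child in node.children:
                new.add(clone(child))
            return new

        return RootedTree(clone(self.root))

    def to_newick(self, lengths: bool = True, internal_labels: bool = True) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                s = node.label
            else:
                s = "(" + ",".join(render(c) for c in node.children) + ")"
                if internal_labels:
                    s += node.label
            if lengths and node.length is not None:
                s += f":{node.length:g}"
            return s

        return render(self.root) + ";"

    def write_newick(self, path, **kw) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(**kw) + "\n")


def _from_dendropy(dtree: dendropy.Tree) -> RootedTree:
    def convert(dnode) -> TreeNode:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        node = TreeNode(label or None, dnode.edge.length)
        for child in dnode.child_nodes():
            node.add(convert(child))
        return node

    return RootedTree(convert(dtree.seed_node))


def parse_newick(text: str) -> RootedTree:
    """Parse a Newick string; unlabeled internals get N1, N2, ... in preorder."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise TreeError(f"Newick parse failure: {exc}") from exc
    return _from_dendropy(dtree)


def read_newick(path) -> RootedTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def root_on_edge(tree: RootedTree, outgroup_label: str) -> RootedTree:
    """Re-root *tree* on the edge subtending *outgroup_label*.

    The outgroup (a leaf or clade-defining internal node) becomes one
    child of the new root. Re-rooting a tree already rooted on that edge
    returns an equivalent copy. Branch lengths on the split edge are
    halved across the two new root edges.
    """
    tree = tree.copy()
    node = tree.find(outgroup_label)
    if node.parent is None:
        raise TreeError(f"cannot root on {outgroup_label!r}: it is already the root")
    if node.parent is tree.root and len(tree.root.children) == 2:
        return tree  # already rooted on this edge

    # Path from the outgroup's parent up to the old root; edges along it
    # are reversed below.
    path: list[TreeNode] = []
    p = node.parent
    while p is not None:
        path.append(p)
        p = p.parent
    old_lengths = [n.length for n in path]

    node.parent.children.remove(node)
    root_label = "ROOT"
    existing = {n.label for n in tree.preorder()}
    i = 1
    while root_label in existing:
        root_label = f"ROOT{i}"
        i += 1
    new_root = TreeNode(root_label)
    half = node.length / 2.0 if node.length is not None else None
    node.length = half
    new_root.add(node)
    new_root.add(path[0])
    path[0].length = half

    for i in range(len(path) - 1):
        child, parent = path[i], path[i + 1]
        parent.children.remove(child)
        child.add(parent)
        parent.length = old_lengths[i]
    path[0].parent = new_root

    # Suppress the old root if edge reversal left it with a single child.
    old_root = path[-1]
    if len(old_root.children) == 1:
        only = old_root.children[0]
        grand = old_root.parent
        assert grand is not None
        idx = grand.children.index(old_root)
        if only.length is not None and old_root.length is not None:
            only.length += old_root.length
        elif old_root.length is not None:
            only.length = old_root.length
        only.parent = grand
        grand.children[idx] = only

    return RootedTree(new_root)


def robinson_foulds(a: RootedTree, b: RootedTree) -> int:
    """Unrooted Robinson–Foulds distance between two trees on the same leaves."""
    taxa = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=a.to_newick(), schema="newick", taxon_namespace=taxa)
    tb = dendropy.Tree.get(data=b.to_newick(), schema="newick", taxon_namespace=taxa)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(ta, tb))


# ---------------------------------------------------------------------------
# Ancestral reconstruction
# ---------------------------------------------------------------------------


@dataclass
class AncestralAssignment:
    """Residue states for every node at every alignment column.

    Leaf states are the observed alignment rows; internal states are the
    parsimony reconstruction (missing symbol where the whole subtree is
    missing). ``scores[c]`` is the parsimony change count of 1-based
    column c+1.
    """

    tree: RootedTree
    states: dict[str, str]
    scores: np.ndarray
    ncol: int = field(init=False)

    def __post_init__(self) -> None:
        self.ncol = len(next(iter(self.states.values())))

    def state(self, node_label: str, col: int) -> str:
        return self.states[node_label][col - 1]


def reconstruct(
    tree: RootedTree,
    aln: MultipleAlignment,
    alphabet: str = AA_ALPHABET,
) -> AncestralAssignment:
    """Assign parsimony states to every internal node for every column.

    Characters outside *alphabet* (gaps, X, stops) are treated as missing:
    they do not constrain the reconstruction, and a subtree that is
    missing everywhere in a column gets the missing symbol.
    """
    for leaf in tree.leaves():
        if leaf.label not in aln:
            raise TreeError(f"leaf {leaf.label!r} has no alignment row")

    ncol = aln.ncol
    nstate = len(alphabet)
    char_to_idx = {c: i for i, c in enumerate(alphabet)}

    in_set: dict[str, np.ndarray] = {}  # label -> (ncol, nstate) candidate sets
    all_missing: dict[str, np.ndarray] = {}
    scores = np.zeros(ncol, dtype=np.int64)

    for node in tree.postorder():
        if node.is_leaf:
            seq = aln[node.label].seq
            idx = np.fromiter(
                (char_to_idx.get(c, -1) for c in seq), count=ncol, dtype=np.int64
            )
            miss = idx < 0
            arr = np.zeros((ncol, nstate), dtype=bool)
            arr[np.arange(ncol), idx.clip(min=0)] = True
            arr[miss] = True  # uninformative: full state set
            in_set[node.label] = arr
            all_missing[node.label] = miss
        else:
            votes = np.zeros((ncol, nstate), dtype=np.int32)
            miss = np.ones(ncol, dtype=bool)
            for child in node.children:
                votes += in_set[child.label]
                miss &= all_missing[child.label]
            mx = votes.max(axis=1)
            in_set[node.label] = votes == mx[:, None]
            all_missing[node.label] = miss
            scores += len(node.children) - mx

    # Columns missing at every leaf carry no changes.
    scores[all_missing[tree.root.label]] = 0

    cols = np.arange(ncol)
    chosen: dict[str, np.ndarray] = {}  # internal label -> state index, -1 = missing
    states: dict[str, str] = {}
    alpha_arr = np.frombuffer(alphabet.encode(), dtype="S1")

    for node in tree.preorder():
        if node.is_leaf:
            states[node.label] = aln[node.label].seq
            seq = states[node.label]
            chosen[node.label] = np.fromiter(
                (char_to_idx.get(c, -1) for c in seq), count=ncol, dtype=np.int64
            )
            continue
        arr = in_set[node.label]
        first = arr.argmax(axis=1)  # alphabetically smallest candidate
        if node.parent is None:
            idx = first
        else:
            par = chosen[node.parent.label]
            inherit = (par >= 0) & arr[cols, par.clip(min=0)]
            idx = np.where(inherit, par, first)
        idx = idx.copy()
        idx[all_missing[node.label]] = -1
        chosen[node.label] = idx
        letters = alpha_arr[idx.clip(min=0)].tobytes().decode()
        states[node.label] = "".join(
            MISSING if i < 0 else letters[k] for k, i in enumerate(idx)
        )

    return AncestralAssignment(tree=tree, states=states, scores=scores)


def write_assignment_tsv(assignment: AncestralAssignment, path) -> None:
    """Serialize as TSV rows (node, column, state), nodes in preorder."""
    with open(path, "w") as fh:
        fh.write("node\tcolumn\tstate\n")
        for node in assignment.tree.preorder():
            seq = assignment.states[node.label]
            for col, state in enumerate(seq, start=1):
                fh.write(f"{node.label}\t{col}\t{state}\n")


def write_ancestral_fasta(assignment: AncestralAssignment, path) -> None:
    """Write one FASTA record per internal node, in preorder."""
    from .seqio import SequenceRecord, write_fasta

    records = [
        SequenceRecord(n.label, assignment.states[n.label])
        for n in assignment.tree.internals()
    ]
    write_fasta(records, path)
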