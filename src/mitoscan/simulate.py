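"""Synthetic ground-truth generators: clade-structured trees, alignments
evolved with planted lineage-specific substitutions, and annotated barcode
panels with known residue spectra and coverage.

Everything is driven by an explicit integer seed through
``numpy.random.default_rng``; regenerating with the same seed reproduces
identical output byte for byte. The substitution process is a uniform
exchange over the 20 amino acids (Poisson event counts per column per
edge); the optional homoplasy-free mode restricts each column to at most
one background event tree-wide and keeps background events off planted
columns, so that parsimony recovery of the planted event list is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqio import AA_ALPHABET, GeneticCode, MultipleAlignment, SequenceRecord, get_code
from .trees import RootedTree, TreeNode

__all__ = [
    "PlantedEvent",
    "SimulationTruth",
    "simulate_tree",
    "evolve_alignment",
    "make_barcode_panel",
    "write_truth_events",
]

Edge = tuple[str, str]


@dataclass(frozen=True)
class PlantedEvent:
    """A substitution forced on the edge above *child* at a 1-based
    column. ``from_aa=None`` accepts whatever the parent state is;
    ``to_aa=None`` picks the alphabetically first residue never yet seen
    in that column (guaranteeing a homoplasy-free, novel state)."""

    child: str
    column: int
    to_aa: str | None = None
    from_aa: str | None = None


@dataclass
class SimulationTruth:
    tree: RootedTree
    states: dict[str, str]  # true sequence at every node
    events: list[tuple[Edge, int, str, str]]  # ((parent, child), column, from, to)
    seed: int
    barcode_spectra: dict[str, dict[str, int]] = field(default_factory=dict)
    barcode_coverage: dict[str, int] = field(default_factory=dict)

    def events_on_edge(self, child: str) -> list[tuple[Edge, int, str, str]]:
        return [ev for ev in self.events if ev[0][1] == child]

    def planted_columns(self) -> set[int]:
        return {ev[1] for ev in self.events}


def _join_random(roots: list[TreeNode], rng: np.random.Generator) -> TreeNode:
    """Random binary joining of subtree roots (coalescent-style)."""
    roots = list(roots)
    while len(roots) > 1:
        i, j = sorted(rng.choice(len(roots), size=2, replace=False).tolist())
        b = roots.pop(j)
        a = roots.pop(i)
        parent = TreeNode()
        a.length = round(float(rng.uniform(0.02, 0.2)), 6)
        b.length = round(float(rng.uniform(0.02, 0.2)), 6)
        parent.add(a)
        parent.add(b)
        roots.append(parent)
    return roots[0]


def simulate_tree(
    n_leaves: int,
    clade_spec: Mapping[str, int] | None = None,
    seed: int = 0,
    outgroup_label: str = "outgroup",
) -> RootedTree:
    """Random rooted binary tree with designated monophyletic clades.

    The root has two children: the outgroup leaf and the ingroup.
    *clade_spec* maps clade name → leaf count; clade leaves are labeled
    ``<clade>_NNN`` and guaranteed monophyletic. Remaining ingroup leaves
    are labeled ``sp_NNN``.
    """
    if n_leaves < 3:
        raise ValueError(f"n_leaves must be >= 3, got {n_leaves}")
    clade_spec = dict(clade_spec or {})
    rng = np.random.default_rng(seed)
    n_clade = sum(clade_spec.values())
    n_free = n_leaves - 1 - n_clade  # one leaf is the outgroup
    if n_free < 0:
        raise ValueError(
            f"clade sizes sum to {n_clade} but only {n_leaves - 1} ingroup leaves exist"
        )
    if any(size < 1 for size in clade_spec.values()):
        raise ValueError("clade sizes must be >= 1")
    units: list[TreeNode] = []
    for clade in sorted(clade_spec):
        leaves = [
            TreeNode(f"{clade}_{i:03d}") for i in range(1, clade_spec[clade] + 1)
        ]
        units.append(_join_random(leaves, rng) if len(leaves) > 1 else leaves[0])
    units.extend(TreeNode(f"sp_{i:03d}") for i in range(1, n_free + 1))
    if not units:
        raise ValueError("no ingroup leaves left after placing the outgroup")
    ingroup = _join_random(units, rng)
    root = TreeNode()
    out = TreeNode(outgroup_label)
    out.length = round(float(rng.uniform(0.02, 0.2)), 6)
    ingroup.length = round(float(rng.uniform(0.02, 0.2)), 6)
    root.add(out)
    root.add(ingroup)
    return RootedTree(root)


def evolve_alignment(
    tree: RootedTree,
    n_columns: int,
    background_rate: float = 0.0,
    planted_events: Sequence[PlantedEvent] = (),
    seed: int = 0,
    homoplasy_free: bool = False,
    background_exclude: Iterable[str] = (),
) -> tuple[MultipleAlignment, SimulationTruth]:
    """Evolve an amino-acid alignment down *tree* and force planted events.

    The root sequence is uniform over the 20 residues. On every edge each
    column receives a Poisson(background_rate) number of uniform
    substitutions, then the edge's planted events are applied (erroring if
    a stated from-residue does not match). In homoplasy-free mode a
    column is hit by at most one background event in the whole tree and
    planted columns receive none. Edges whose child label appears in
    *background_exclude* receive no background events at all (so their
    true event list is exactly what was planted).
    """
    if background_rate < 0:
        raise ValueError("background_rate must be >= 0")
    alphabet = np.frombuffer(AA_ALPHABET.encode(), dtype="S1")
    nstate = len(alphabet)
    rng = np.random.default_rng(seed)

    by_child: dict[str, list[PlantedEvent]] = {}
    for ev in planted_events:
        if not 1 <= ev.column <= n_columns:
            raise ValueError(f"planted column {ev.column} outside 1..{n_columns}")
        tree.find(ev.child)  # raises if absent
        by_child.setdefault(ev.child, []).append(ev)

    planted_cols = {ev.column for ev in planted_events}
    touched: set[int] = set(planted_cols)
    excluded_edges = set(background_exclude)

    root_label = tree.root.label
    seqs: dict[str, np.ndarray] = {
        root_label: rng.integers(0, nstate, size=n_columns)
    }
    # Residues ever seen per planted column, for novel-state planting.
    seen: dict[int, set[str]] = {
        col: {alphabet[seqs[root_label][col - 1]].decode()} for col in planted_cols
    }
    events: list[tuple[Edge, int, str, str]] = []

    for node in tree.preorder():
        if node.parent is None:
            continue
        seq = seqs[node.parent.label].copy()
        edge = (node.parent.label, node.label)
        counts = rng.poisson(background_rate, size=n_columns)
        # Changes on the two root-incident edges cannot be polarized by
        # parsimony (the root has no further outgroup), so the exact-recovery
        # mode keeps background events off them.
        skip_edge = (homoplasy_free and node.parent is tree.root) or (
            node.label in excluded_edges
        )
        for col0 in np.flatnonzero(counts) if not skip_edge else ():
            col = int(col0) + 1
            n_events = int(counts[col0])
            if homoplasy_free:
                if col in touched:
                    continue  # reject: column already used elsewhere
                touched.add(col)
                n_events = 1
            for _ in range(n_events):
                old = int(seq[col0])
                new = int((old + 1 + rng.integers(0, nstate - 1)) % nstate)
                events.append(
                    (edge, col, alphabet[old].decode(), alphabet[new].decode())
                )
                seq[col0] = new
                if col in seen:
                    seen[col].add(alphabet[new].decode())
        for ev in by_child.get(node.label, ()):
            old = alphabet[seq[ev.column - 1]].decode()
            if ev.from_aa is not None and old != ev.from_aa:
                raise ValueError(
                    f"planted event at column {ev.column} on edge to {ev.child!r}: "
                    f"parent state is {old}, expected {ev.from_aa}"
                )
            if ev.to_aa is None:
                candidates = [a for a in AA_ALPHABET if a not in seen[ev.column]]
                if not candidates:
                    raise ValueError(
                        f"column {ev.column} has exhausted all 20 residues"
                    )
                to_aa = candidates[0]
            else:
                to_aa = ev.to_aa
            if old == to_aa:
                raise ValueError(
                    f"planted event at column {ev.column} on edge to {ev.child!r} "
                    f"is a no-op ({old}->{to_aa})"
                )
            events.append((edge, ev.column, old, to_aa))
            seq[ev.column - 1] = AA_ALPHABET.index(to_aa)
            seen[ev.column].add(to_aa)
        seqs[node.label] = seq

    states = {
        label: arr_to_str(arr, alphabet) for label, arr in seqs.items()
    }
    aln = MultipleAlignment(
        [SequenceRecord(leaf, states[leaf]) for leaf in tree.leaf_labels()]
    )
    truth = SimulationTruth(tree=tree, states=states, events=events, seed=seed)
    return aln, truth


def arr_to_str(arr: np.ndarray, alphabet: np.ndarray) -> str:
    return alphabet[arr].tobytes().decode()


def make_barcode_panel(
    clade_proteins: Mapping[str, str],
    clade_spectra: Mapping[str, Mapping[str, int]],
    focal_ref_position: int,
    coverage: float = 1.0,
    code: GeneticCode | str | int = "vertebrate-mitochondrial",
    seed: int = 0,
    flank: int = 40,
) -> tuple[list[SequenceRecord], dict[str, str], SimulationTruth | None, dict]:
    """Nucleotide barcode fragments with planted residue spectra.

    For each clade, samples carry the clade's base protein with the focal
    reference position replaced per the requested spectrum, back-translated
    through random synonymous codons. A ``coverage`` fraction of each
    clade's samples (rounded) gets a fragment spanning the focal position
    (± *flank* residues, clipped); the rest are truncated before it.

    Returns (records, annotations id→clade, None, truth_dict) where
    truth_dict has per-clade expected informative spectra and coverage
    counts.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must lie in [0, 1]")
    code = get_code(code)
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    annotations: dict[str, str] = {}
    truth_spectra: dict[str, dict[str, int]] = {}
    truth_cover: dict[str, int] = {}

    for clade in sorted(clade_spectra):
        base = clade_proteins[clade]
        focal0 = focal_ref_position - 1
        if not 0 <= focal0 < len(base):
            raise ValueError(
                f"focal position {focal_ref_position} outside clade {clade!r} protein"
            )
        residues: list[str] = []
        for res in sorted(clade_spectra[clade]):
            count = clade_spectra[clade][res]
            if count < 0:
                raise ValueError(f"negative count for {clade}/{res}")
            residues.extend([res] * count)
        n = len(residues)
        n_cover = int(round(coverage * n))
        covering = np.zeros(n, dtype=bool)
        covering[rng.permutation(n)[:n_cover]] = True
        spectrum: dict[str, int] = {}
        for i, (res, covers) in enumerate(zip(residues, covering), start=1):
            protein = base[:focal0] + res + base[focal0 + 1 :]
            if covers:
                lo = max(0, focal0 - flank)
                hi = min(len(protein), focal0 + flank + 1)
                spectrum[res] = spectrum.get(res, 0) + 1
            elif focal0 > 0:
                lo, hi = 0, focal0  # ends just before the focal residue
            else:
                lo, hi = 1, len(protein)
            fragment = protein[lo:hi]
            nt = _back_translate(fragment, code, rng)
            sample_id = f"{clade}_{i:05d}"
            records.append(SequenceRecord(sample_id, nt))
            annotations[sample_id] = clade
        truth_spectra[clade] = spectrum
        truth_cover[clade] = n_cover

    truth = {"spectra": truth_spectra, "coverage": truth_cover}
    return records, annotations, None, truth


def _back_translate(protein: str, code: GeneticCode, rng: np.random.Generator) -> str:
    out = []
    for aa in protein:
        codons = code.codons_for(aa)
        out.append(codons[int(rng.integers(0, len(codons)))])
    return "".join(out)


def write_truth_events(truth: SimulationTruth, path) -> None:
    """TSV of planted/background events: parent, child, column, from, to."""
    with open(path, "w") as fh:
        fh.write("parent\tchild\tcolumn\tfrom\tto\n")
        for (parent, child), col, old, new in truth.events:
            fh.write(f"{parent}\t{child}\t{col}\t{old}\t{new}\n")
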