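"""Sequence I/O, mitochondrial genetic codes, translation, and proteome
concatenation.

FASTA parsing/writing is delegated to Biopython; the genetic code tables
are embedded constants (NCBI translation tables 1, 2 and 5) so that no
network access is ever required.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = [
    "AA_ALPHABET",
    "NT_ALPHABET",
    "GAP",
    "MISSING",
    "STOP",
    "SequenceRecord",
    "MultipleAlignment",
    "GeneticCode",
    "GENETIC_CODES",
    "get_code",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "translate",
    "choose_frame",
    "min_codon_distance",
    "concatenate_proteomes",
    "write_offsets",
]

#: The 20 standard amino acids, alphabetically ordered. Index order doubles
#: as the deterministic tie-break order used throughout the pipeline.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET = "ACGTN"
GAP = "-"
MISSING = "X"
STOP = "*"

_AA_LEGAL = frozenset(AA_ALPHABET + MISSING + STOP + GAP)
_NT_LEGAL = frozenset(NT_ALPHABET + GAP)


class SequenceError(ValueError):
    """Raised on malformed or inconsistent sequence input."""


@dataclass
class SequenceRecord:
    """One named sequence plus free-form annotations (clade labels etc.)."""

    id: str
    seq: str
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence record with empty id")
        if not self.seq:
            raise SequenceError(f"sequence record {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.seq)

    def ungapped(self) -> str:
        return self.seq.replace(GAP, "")


class MultipleAlignment:
    """An aligned residue matrix. Columns are 1-based throughout."""

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if len(records) < 2:
            raise SequenceError("alignment needs at least 2 rows")
        ncol = len(records[0].seq)
        for rec in records:
            if len(rec.seq) != ncol:
                raise SequenceError(
                    f"row {rec.id!r} has length {len(rec.seq)}, expected {ncol}"
                )
        if ncol < 1:
            raise SequenceError("alignment has zero columns")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SequenceError(f"duplicate alignment row id(s): {', '.join(dup)}")
        self.records = records
        self.ncol = ncol
        self._index = {r.id: r for r in records}

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._index

    def __getitem__(self, rec_id: str) -> SequenceRecord:
        try:
            return self._index[rec_id]
        except KeyError:
            raise KeyError(f"no alignment row named {rec_id!r}") from None

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def column(self, col: int) -> str:
        """Residues of 1-based column *col*, in row order."""
        if not 1 <= col <= self.ncol:
            raise IndexError(f"column {col} out of range 1..{self.ncol}")
        return "".join(r.seq[col - 1] for r in self.records)


@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry codon→amino-acid map; stops map to '*'."""

    code_id: str
    ncbi_id: int
    table: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"genetic code {self.code_id} has {len(self.table)} codons")

    def codons_for(self, aa: str) -> tuple[str, ...]:
        """All codons encoding *aa* (raises if the code never encodes it)."""
        hits = tuple(c for c, a in self.table.items() if a == aa)
        if not hits:
            raise SequenceError(f"amino acid {aa!r} is not encoded by {self.code_id}")
        return hits


def _build_table(aas: str) -> dict[str, str]:
    codons = ["".join(c) for c in itertools.product("TCAG", repeat=3)]
    return dict(zip(codons, aas))


# NCBI translation tables, codons in TCAG order (TTT, TTC, TTA, ...).
_NCBI_TABLES = {
    1: "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG",
    2: "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSS**VVVVAAAADDEEGGGG",
    5: "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSSSSVVVVAAAADDEEGGGG",
}

GENETIC_CODES: dict[str, GeneticCode] = {
    "standard": GeneticCode("standard", 1, _build_table(_NCBI_TABLES[1])),
    "vertebrate-mitochondrial": GeneticCode(
        "vertebrate-mitochondrial", 2, _build_table(_NCBI_TABLES[2])
    ),
    "invertebrate-mitochondrial": GeneticCode(
        "invertebrate-mitochondrial", 5, _build_table(_NCBI_TABLES[5])
    ),
}

_CODE_ALIASES = {"1": "standard", "2": "vertebrate-mitochondrial", "5": "invertebrate-mitochondrial"}


def get_code(code_id: str | int | GeneticCode) -> GeneticCode:
    """Resolve a genetic code by name, NCBI table number, or identity."""
    if isinstance(code_id, GeneticCode):
        return code_id
    key = str(code_id)
    key = _CODE_ALIASES.get(key, key)
    try:
        return GENETIC_CODES[key]
    except KeyError:
        known = ", ".join(sorted(GENETIC_CODES) | _CODE_ALIASES.keys())
        raise SequenceError(f"unknown genetic code {code_id!r}; known: {known}") from None


def _normalize(seq: str) -> str:
    return seq.upper().replace(".", GAP)


def read_fasta(path: str | Path, alphabet: str = "aa") -> list[SequenceRecord]:
    """Read a FASTA file into validated, upper-cased SequenceRecords.

    *alphabet* is ``"aa"`` (amino acids, gap, X, stop) or ``"nt"``
    (A/C/G/T/N and gap). Duplicate ids, an empty file, or illegal
    characters raise :class:`SequenceError`.
    """
    if alphabet not in ("aa", "nt"):
        raise ValueError(f"alphabet must be 'aa' or 'nt', got {alphabet!r}")
    legal = _AA_LEGAL if alphabet == "aa" else _NT_LEGAL
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        seq = _normalize(str(bio.seq))
        if bio.id in seen:
            raise SequenceError(f"duplicate sequence id {bio.id!r} in {path}")
        seen.add(bio.id)
        bad = sorted(set(seq) - legal)
        if bad:
            raise SequenceError(
                f"illegal character(s) {' '.join(bad)} in record {bio.id!r} ({path})"
            )
        records.append(SequenceRecord(bio.id, seq))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = [_BioRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width or None)
        writer.write_file(bio)


def read_annotations(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a TSV annotation table (header row; column 1 = sequence id).

    Returns id → {column name → label}.
    """
    out: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise SequenceError(f"annotation table {path} needs id + >=1 label column")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            sid = fields[0]
            if sid in out:
                raise SequenceError(f"duplicate sample id {sid!r} at {path}:{lineno}")
            out[sid] = dict(zip(header[1:], fields[1:]))
    return out


def translate(seq: str, code: GeneticCode | str | int, frame: int = 1) -> str:
    """Translate a nucleotide string codon by codon.

    Codons containing N or a gap translate to 'X'; stops to '*'; a
    trailing partial codon is dropped.
    """
    if frame not in (1, 2, 3):
        raise ValueError(f"frame must be 1, 2, or 3, got {frame}")
    code = get_code(code)
    seq = _normalize(seq)
    bad = sorted(set(seq) - _NT_LEGAL)
    if bad:
        raise SequenceError(f"illegal nucleotide character(s): {' '.join(bad)}")
    body = seq[frame - 1 :]
    out = []
    for i in range(0, len(body) - len(body) % 3, 3):
        codon = body[i : i + 3]
        out.append(code.table.get(codon, MISSING))
    return "".join(out)


def choose_frame(seq: str, code: GeneticCode | str | int) -> tuple[int, str]:
    """Translate in all three frames; return (frame, protein) minimizing
    internal stop codons. Ties break to the lowest frame number."""
    code = get_code(code)
    best: tuple[int, int, str] | None = None
    for frame in (1, 2, 3):
        prot = translate(seq, code, frame)
        stops = prot[:-1].count(STOP) if prot else 0
        if best is None or stops < best[0]:
            best = (stops, frame, prot)
    assert best is not None
    return best[1], best[2]


def min_codon_distance(aa1: str, aa2: str, code: GeneticCode | str | int) -> int:
    """Minimum Hamming distance between any codon of *aa1* and any codon of
    *aa2* under *code*."""
    code = get_code(code)
    best = 3
    for c1 in code.codons_for(aa1):
        for c2 in code.codons_for(aa2):
            d = sum(a != b for a, b in zip(c1, c2))
            if d < best:
                best = d
    return best


def concatenate_proteomes(
    per_species: Mapping[str, Mapping[str, SequenceRecord]],
    gene_order: Sequence[str],
    missing_policy: str = "strict",
) -> tuple[list[SequenceRecord], dict[str, tuple[int, int]]]:
    """Concatenate per-gene records into one record per species.

    Every gene must have a single consistent length across species (the
    inputs are per-gene alignment rows). Under ``missing_policy="strict"``
    an absent gene is an error; under ``"pad"`` it is filled with gaps.

    Returns (records, offsets) where offsets maps gene → (start, end),
    1-based inclusive positions within the concatenation.
    """
    if missing_policy not in ("strict", "pad"):
        raise ValueError(f"missing_policy must be 'strict' or 'pad', got {missing_policy!r}")
    if not gene_order:
        raise ValueError("gene_order is empty")
    gene_len: dict[str, int] = {}
    for species, genes in per_species.items():
        for gene in gene_order:
            if gene in genes:
                n = len(genes[gene].seq)
                if gene_len.setdefault(gene, n) != n:
                    raise SequenceError(
                        f"gene {gene!r} length mismatch: {n} in {species!r} vs "
                        f"{gene_len[gene]} elsewhere"
                    )
    for gene in gene_order:
        if gene not in gene_len:
            raise SequenceError(f"gene {gene!r} absent from every species")
    offsets: dict[str, tuple[int, int]] = {}
    pos = 1
    for gene in gene_order:
        offsets[gene] = (pos, pos + gene_len[gene] - 1)
        pos += gene_len[gene]
    out = []
    for species, genes in per_species.items():
        parts = []
        for gene in gene_order:
            if gene in genes:
                parts.append(genes[gene].seq)
            elif missing_policy == "pad":
                parts.append(GAP * gene_len[gene])
            else:
                raise SequenceError(f"species {species!r} is missing gene {gene!r}")
        out.append(SequenceRecord(species, "".join(parts)))
    return out, offsets


def write_offsets(offsets: Mapping[str, tuple[int, int]], path: str | Path) -> None:
    """Write the per-gene offset table as TSV (gene, start, end; 1-based)."""
    with open(path, "w") as fh:
        fh.write("gene\tstart\tend\n")
        for gene, (start, end) in offsets.items():
            fh.write(f"{gene}\t{start}\t{end}\n")
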