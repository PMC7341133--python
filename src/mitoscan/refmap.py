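"""Mapping between alignment columns and the ungapped residue numbering of
a designated reference row (e.g. the bovine numbering convention)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .seqio import GAP, MultipleAlignment
from .edge_scan import EdgeReport

__all__ = [
    "ReferenceMap",
    "build_reference_map",
    "annotate_with_reference",
    "gene_position",
    "write_reference_map_tsv",
]


@dataclass
class ReferenceMap:
    """Partial, strictly increasing map alignment column → reference
    position (both 1-based), defined exactly where the reference row is
    ungapped, plus its inverse."""

    ref_id: str
    col_to_ref: dict[int, int]
    ref_to_col: dict[int, int] = field(init=False)

    def __post_init__(self) -> None:
        self.ref_to_col = {v: k for k, v in self.col_to_ref.items()}

    def ref_length(self) -> int:
        return len(self.col_to_ref)

    def column_of(self, ref_position: int) -> int:
        try:
            return self.ref_to_col[ref_position]
        except KeyError:
            raise KeyError(
                f"reference position {ref_position} outside 1..{self.ref_length()} "
                f"of {self.ref_id!r}"
            ) from None


def build_reference_map(aln: MultipleAlignment, ref_id: str) -> ReferenceMap:
    """Map the k-th non-gap column of row *ref_id* to reference position k."""
    row = aln[ref_id].seq  # raises KeyError if absent
    col_to_ref: dict[int, int] = {}
    pos = 0
    for col, char in enumerate(row, start=1):
        if char != GAP:
            pos += 1
            col_to_ref[col] = pos
    return ReferenceMap(ref_id=ref_id, col_to_ref=col_to_ref)


def annotate_with_reference(
    target: EdgeReport | Sequence[int], refmap: ReferenceMap
) -> EdgeReport | list[int | None]:
    """Attach reference positions (None where the reference is gapped).

    For an :class:`EdgeReport` the annotation is stored in-place on
    ``reference_positions`` and the report returned; for a plain column
    list, a parallel list of positions is returned.
    """
    if isinstance(target, EdgeReport):
        target.reference_positions = [
            refmap.col_to_ref.get(col) for col, _, _ in target.entries
        ]
        return target
    return [refmap.col_to_ref.get(col) for col in target]


def gene_position(
    ref_position: int, offsets: Mapping[str, tuple[int, int]]
) -> tuple[str, int]:
    """Express a concatenated reference position as (gene, within-gene
    position) using a per-gene offset table (1-based inclusive)."""
    for gene, (start, end) in offsets.items():
        if start <= ref_position <= end:
            return gene, ref_position - start + 1
    raise KeyError(f"reference position {ref_position} outside every gene range")


def write_reference_map_tsv(
    refmap: ReferenceMap,
    path,
    offsets: Mapping[str, tuple[int, int]] | None = None,
) -> None:
    """TSV (column, gene, reference_position); gene '.' without offsets."""
    with open(path, "w") as fh:
        fh.write("column\tgene\treference_position\n")
        for col in sorted(refmap.col_to_ref):
            ref = refmap.col_to_ref[col]
            if offsets is not None:
                gene, within = gene_position(ref, offsets)
                fh.write(f"{col}\t{gene}\t{within}\n")
            else:
                fh.write(f"{col}\t.\t{ref}\n")
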