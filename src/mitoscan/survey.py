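"""Clade-wise fixation surveys of residue states at one reference position.

Samples arrive either as rows of the reference alignment (amino acid,
shared coordinates) or as unaligned nucleotide barcode fragments, which
are translated (best reading frame by fewest internal stops) and placed
onto the ungapped reference protein with a local affine-gap BLOSUM62
alignment — the only alignment computed in this package.

A sample is *informative* for a position iff its placed residue there is
one of the 20 standard amino acids (not a gap, not X/stop, not missing
coverage). Informative counts form per-clade residue spectra, classified
as fixed / unfixed / absent against a configurable fixation threshold
(default 1.0).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .refmap import ReferenceMap
from .seqio import AA_ALPHABET, GeneticCode, SequenceRecord, choose_frame, get_code

__all__ = [
    "FixationState",
    "FixationReport",
    "classify_fixation",
    "place_barcode",
    "survey_position",
    "merge_reports",
    "rank_substituted_clades",
    "write_fixation_tsv",
]

_STANDARD = frozenset(AA_ALPHABET)


@dataclass(frozen=True)
class FixationState:
    kind: str  # "fixed" | "unfixed" | "absent"
    residue: str | None = None
    derived: bool | None = None

    def __str__(self) -> str:
        if self.kind == "fixed":
            tag = "derived-fixed" if self.derived else "fixed"
            return f"{tag}({self.residue})"
        return self.kind


@dataclass
class FixationReport:
    """Residue frequency spectrum of one clade at one reference position."""

    ref_position: int
    clade: str
    n_total: int
    n_informative: int
    spectrum: Counter
    fixation_state: FixationState = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if sum(self.spectrum.values()) != self.n_informative:
            raise ValueError("spectrum does not sum to n_informative")
        if self.n_informative > self.n_total:
            raise ValueError("n_informative exceeds n_total")


def classify_fixation(
    spectrum: Mapping[str, int],
    ancestral_residue: str | None,
    threshold: float = 1.0,
) -> FixationState:
    """Classify a residue spectrum.

    fixed(r) iff count(r)/n_informative >= threshold; flagged derived when
    r differs from the ancestral residue. Empty spectra are absent.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0.5, 1.0], got {threshold}")
    n = sum(spectrum.values())
    if n == 0:
        return FixationState("absent")
    # threshold > 0.5 ⇒ at most one residue can qualify; alphabetical tie-break
    top = min(spectrum, key=lambda r: (-spectrum[r], r))
    if spectrum[top] / n >= threshold:
        derived = None if ancestral_residue is None else top != ancestral_residue
        return FixationState("fixed", residue=top, derived=derived)
    return FixationState("unfixed")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "local"
    return aligner


def place_barcode(
    barcode_nt: str,
    reference_protein: str,
    code: GeneticCode | str | int = "vertebrate-mitochondrial",
    aligner: Align.PairwiseAligner | None = None,
) -> dict[int, str]:
    """Translate a nucleotide barcode and align it to the ungapped
    reference protein; return reference position (1-based) → residue for
    every reference position the fragment covers."""
    _, protein = choose_frame(barcode_nt, get_code(code))
    if not protein:
        return {}
    if aligner is None:
        aligner = _make_aligner()
    try:
        alignment = aligner.align(reference_protein, protein)[0]
    except (IndexError, ValueError):
        return {}
    placed: dict[int, str] = {}
    for (ts, te), (qs, qe) in zip(*alignment.aligned):
        for off in range(te - ts):
            placed[ts + off + 1] = protein[qs + off]
    return placed


def survey_position(
    samples: Sequence[SequenceRecord],
    annotations: Mapping[str, str] | Mapping[str, Mapping[str, str]],
    ref_position: int,
    *,
    refmap: ReferenceMap | None = None,
    reference_protein: str | None = None,
    code: GeneticCode | str | int = "vertebrate-mitochondrial",
    clade_field: str | None = None,
    ancestral: str | None = None,
    threshold: float = 1.0,
    exclude: Iterable[str] = (),
) -> dict[str, FixationReport]:
    """Per-clade residue spectra at *ref_position*.

    With *refmap*, samples are pre-aligned amino-acid rows in the map's
    alignment coordinates; with *reference_protein*, samples are
    nucleotide barcodes placed by pairwise alignment. Samples not
    covering the position, or ambiguous there, count toward n_total but
    not n_informative. *exclude* drops samples (e.g. known
    mis-annotations) entirely.
    """
    if (refmap is None) == (reference_protein is None):
        raise ValueError("provide exactly one of refmap or reference_protein")
    excluded = set(exclude)

    def clade_of(sample_id: str) -> str:
        try:
            ann = annotations[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} has no annotation") from None
        if isinstance(ann, Mapping):
            if clade_field is None:
                raise ValueError("clade_field required for multi-column annotations")
            return ann[clade_field]
        return ann

    if refmap is not None:
        column = refmap.column_of(ref_position)  # raises if unmapped

    aligner = _make_aligner() if reference_protein is not None else None

    totals: Counter = Counter()
    spectra: dict[str, Counter] = {}
    for rec in samples:
        if rec.id in excluded:
            continue
        clade = clade_of(rec.id)
        totals[clade] += 1
        spectra.setdefault(clade, Counter())
        if refmap is not None:
            residue = rec.seq[column - 1] if len(rec.seq) >= column else None
        else:
            residue = place_barcode(rec.seq, reference_protein, code, aligner).get(
                ref_position
            )
        if residue is not None and residue in _STANDARD:
            spectra[clade][residue] += 1

    reports = {}
    for clade in sorted(totals):
        spectrum = spectra[clade]
        reports[clade] = FixationReport(
            ref_position=ref_position,
            clade=clade,
            n_total=totals[clade],
            n_informative=sum(spectrum.values()),
            spectrum=spectrum,
            fixation_state=classify_fixation(spectrum, ancestral, threshold),
        )
    return reports


def merge_reports(a: FixationReport, b: FixationReport, threshold: float = 1.0,
                  ancestral: str | None = None) -> FixationReport:
    """Componentwise sum of two reports over disjoint sample sets."""
    if a.ref_position != b.ref_position:
        raise ValueError("reports describe different reference positions")
    spectrum = a.spectrum + b.spectrum
    return FixationReport(
        ref_position=a.ref_position,
        clade=a.clade if a.clade == b.clade else f"{a.clade}+{b.clade}",
        n_total=a.n_total + b.n_total,
        n_informative=a.n_informative + b.n_informative,
        spectrum=spectrum,
        fixation_state=classify_fixation(spectrum, ancestral, threshold),
    )


def rank_substituted_clades(
    reports: Mapping[str, FixationReport], ancestral: str
) -> tuple[pd.DataFrame, dict]:
    """Clades with any informative non-ancestral sample, ranked by derived
    fraction (descending; ties by clade label), plus the overall divergent
    count and fraction across all reports."""
    rows = []
    total_informative = 0
    total_derived = 0
    for clade, rep in reports.items():
        derived = rep.n_informative - rep.spectrum.get(ancestral, 0)
        total_informative += rep.n_informative
        total_derived += derived
        if derived > 0:
            rows.append(
                {
                    "clade": clade,
                    "n_total": rep.n_total,
                    "n_informative": rep.n_informative,
                    "n_derived": derived,
                    "derived_fraction": derived / rep.n_informative,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["clade", "n_total", "n_informative", "n_derived", "derived_fraction"],
    )
    if not df.empty:
        df = df.sort_values(
            ["derived_fraction", "clade"], ascending=[False, True]
        ).reset_index(drop=True)
    overall = {
        "divergent": total_derived,
        "informative": total_informative,
        "fraction": (total_derived / total_informative) if total_informative else 0.0,
    }
    return df, overall


def write_fixation_tsv(reports: Mapping[str, FixationReport], path) -> None:
    """Per-clade TSV: clade, n_total, n_informative, spectrum, state."""
    with open(path, "w") as fh:
        fh.write("clade\tref_position\tn_total\tn_informative\tspectrum\tfixation_state\n")
        for clade in sorted(reports):
            rep = reports[clade]
            spec = ",".join(
                f"{res}:{cnt}" for res, cnt in sorted(rep.spectrum.items())
            )
            fh.write(
                f"{clade}\t{rep.ref_position}\t{rep.n_total}\t{rep.n_informative}\t"
                f"{spec or '.'}\t{rep.fixation_state}\n"
            )
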