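"""Inter-residue distances in a macromolecular structure, for annotating
candidate positions relative to proton-channel landmark residues.

Distances follow the minimum heavy-atom convention: the smallest
Euclidean distance over all pairs of non-hydrogen atoms, one atom drawn
from each residue. PDB and mmCIF files are parsed with biotite.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from biotite.structure import AtomArray
from biotite.structure.io import pdb as _pdb
from biotite.structure.io import pdbx as _pdbx
from scipy.spatial.distance import cdist

__all__ = [
    "StructureError",
    "StructureModel",
    "read_structure",
    "min_residue_distance",
    "annotate_candidates",
]


class StructureError(ValueError):
    """Raised on unusable structure input or missing residues."""


@dataclass
class StructureModel:
    """A set of (heavy) atoms with chain, residue and coordinate fields."""

    atoms: AtomArray

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.atoms.chain_id:
            seen.setdefault(str(c))
        return list(seen)

    def residue_atoms(self, chain: str, res_number: int) -> AtomArray:
        mask = (self.atoms.chain_id == chain) & (self.atoms.res_id == res_number)
        sub = self.atoms[mask]
        if len(sub) == 0:
            raise StructureError(f"residue {res_number} not found in chain {chain!r}")
        return sub

    def has_residue(self, chain: str, res_number: int) -> bool:
        return bool(
            np.any((self.atoms.chain_id == chain) & (self.atoms.res_id == res_number))
        )

    def default_chain(self, residues: Sequence[int]) -> str:
        """First chain (file order) containing every residue in *residues*."""
        for chain in self.chains:
            if all(self.has_residue(chain, r) for r in residues):
                return chain
        raise StructureError(
            f"no chain contains all residues {list(residues)}; chains: {self.chains}"
        )


def read_structure(path: str | Path, keep_hydrogens: bool = False) -> StructureModel:
    """Read a PDB or mmCIF file (first model).

    Hydrogens are dropped unless *keep_hydrogens*; alternate locations are
    resolved to the highest-occupancy conformer (ties keep the first,
    i.e. altloc 'A').
    """
    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif", ".pdbx"):
        cif = _pdbx.CIFFile.read(str(path))
        atoms = _pdbx.get_structure(cif, model=1, altloc="occupancy")
    else:
        pdb_file = _pdb.PDBFile.read(str(path))
        atoms = _pdb.get_structure(pdb_file, model=1, altloc="occupancy")
    if not keep_hydrogens:
        atoms = atoms[~np.isin(atoms.element, ("H", "D"))]
    if len(atoms) == 0:
        raise StructureError(f"no atoms read from {path}")
    if not np.all(np.isfinite(atoms.coord)):
        raise StructureError(f"non-finite coordinates in {path}")
    return StructureModel(atoms=atoms)


def min_residue_distance(
    model: StructureModel, chain: str, res_a: int, res_b: int
) -> float:
    """Minimum heavy-atom Euclidean distance (Å) between two residues of
    one chain. Zero when res_a == res_b."""
    a = model.residue_atoms(chain, res_a)
    b = model.residue_atoms(chain, res_b)
    if res_a == res_b:
        return 0.0
    return float(cdist(a.coord, b.coord).min())


def annotate_candidates(
    model: StructureModel,
    chain: str | None,
    positions: Sequence[int],
    landmarks: Sequence[int],
) -> pd.DataFrame:
    """|positions| × |landmarks| table of minimum heavy-atom distances.

    With chain=None, the first chain containing every queried residue is
    used.
    """
    if chain is None:
        chain = model.default_chain(list(positions) + list(landmarks))
    data = {
        lm: [min_residue_distance(model, chain, pos, lm) for pos in positions]
        for lm in landmarks
    }
    return pd.DataFrame(data, index=list(positions), columns=list(landmarks))
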