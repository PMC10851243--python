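"""Carhart-style atom codes and canonical atom-pair enumeration.

An atom pair is the classic topological-fingerprint unit: two atom codes
plus the length in bonds of the shortest path between the atoms.  Each
heavy atom is coded by its element, the number of non-hydrogen neighbours,
and the number of electrons it contributes to pi bonding.  Hydrogens never
receive codes and never enter pairs.

The pi-electron convention used here is: an aromatic atom contributes one
pi electron (plus any exocyclic unsaturation), and a non-aromatic atom
contributes ``sum(bond order - 1)`` over its bonds.  On ring atoms this is
the Kekule-rounded value (a benzene carbon -> 1, a naphthalene ring-fusion
carbon -> 1) and it is independent of atom input order, so canonical pair
multisets are invariant under SMILES rewriting.
"""

from __future__ import annotations

import warnings
from collections import Counter
from typing import NamedTuple, Union

from rdkit import Chem

__all__ = [
    "AtomCode",
    "PairCode",
    "PairMultiset",
    "DisconnectedAtomsError",
    "mol_from_smiles",
    "atom_code",
    "topological_distance",
    "enumerate_pairs",
]

#: Upper bound (in bonds) on the topological distance of an enumerated pair.
DEFAULT_MAX_DISTANCE = 4

# RDKit encodes "no path" in the distance matrix as a huge sentinel.
_NO_PATH = 1.0e7


class DisconnectedAtomsError(ValueError):
    """Raised when a topological distance is requested across fragments."""


class AtomCode(NamedTuple):
    """Identity of a heavy atom: (element, heavy degree, pi electrons)."""

    element: str
    heavy_degree: int
    pi_electrons: int

    def __str__(self) -> str:  # "C.2.1"
        return f"{self.element}.{self.heavy_degree}.{self.pi_electrons}"

    @classmethod
    def from_string(cls, text: str) -> "AtomCode":
        element, degree, pi = text.split(".")
        return cls(element, int(degree), int(pi))


class PairCode(NamedTuple):
    """Canonical identity of an atom pair.

    The two codes are stored in lexicographic order on
    (element, heavy_degree, pi_electrons), so ``PairCode.make(a, b, d)``
    equals ``PairCode.make(b, a, d)``.
    """

    code_lo: AtomCode
    code_hi: AtomCode
    distance: int

    @classmethod
    def make(cls, a: AtomCode, b: AtomCode, distance: int) -> "PairCode":
        if distance < 1:
            raise ValueError(f"pair distance must be >= 1, got {distance}")
        lo, hi = sorted((a, b))
        return cls(lo, hi, int(distance))

    def __str__(self) -> str:  # "C.1.0-C.2.0@1"
        return f"{self.code_lo}-{self.code_hi}@{self.distance}"

    @classmethod
    def from_string(cls, text: str) -> "PairCode":
        codes, distance = text.rsplit("@", 1)
        lo, hi = codes.split("-")
        return cls.make(AtomCode.from_string(lo), AtomCode.from_string(hi), int(distance))


#: Multiset of canonical pair codes with occurrence counts.
PairMultiset = Counter  # Counter[PairCode]

MoleculeLike = Union[str, Chem.Mol]


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse and sanitize a SMILES string, stripping explicit hydrogens.

    Raises ``ValueError`` if RDKit cannot parse or sanitize the input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Chem.RemoveHs(mol)


def _as_mol(molecule: MoleculeLike) -> Chem.Mol:
    if isinstance(molecule, str):
        return mol_from_smiles(molecule)
    return molecule


def _pi_electrons(atom: Chem.Atom) -> int:
    pi = 0
    for bond in atom.GetBonds():
        if bond.GetIsAromatic():
            continue
        pi += max(0, int(round(bond.GetBondTypeAsDouble())) - 1)
    if atom.GetIsAromatic():
        pi += 1
    return pi


def atom_code(molecule: MoleculeLike, atom_index: int) -> AtomCode:
    """Compute the three-component code of one heavy atom.

    Implicit and explicit hydrogens are excluded from the degree; asking for
    the code of a hydrogen atom is an error.  Charges, isotopes and
    stereochemistry do not enter the code.
    """
    mol = _as_mol(molecule)
    if not 0 <= atom_index < mol.GetNumAtoms():
        raise IndexError(f"atom index {atom_index} out of range")
    atom = mol.GetAtomWithIdx(atom_index)
    if atom.GetAtomicNum() == 1:
        raise ValueError("hydrogen atoms do not receive atom codes")
    heavy_degree = sum(1 for nbr in atom.GetNeighbors() if nbr.GetAtomicNum() > 1)
    return AtomCode(atom.GetSymbol(), heavy_degree, _pi_electrons(atom))


def topological_distance(molecule: MoleculeLike, i: int, j: int) -> int:
    """Length in bonds of the shortest path between heavy atoms i and j.

    Raises ``DisconnectedAtomsError`` if the atoms lie in different
    fragments, so "no path" can never be confused with a valid distance.
    """
    mol = _as_mol(molecule)
    if i == j:
        raise ValueError("topological distance requires two distinct atoms")
    dmat = Chem.GetDistanceMatrix(mol)
    d = dmat[i, j]
    if d >= _NO_PATH:
        raise DisconnectedAtomsError(f"atoms {i} and {j} are in different fragments")
    return int(d)


def enumerate_pairs(
    molecule: MoleculeLike, max_distance: int = DEFAULT_MAX_DISTANCE
) -> "Counter[PairCode]":
    """Enumerate all canonical atom pairs within ``max_distance`` bonds.

    Every unordered pair of heavy atoms at topological distance 1..max_distance
    contributes one count to its canonical :class:`PairCode`.  The result is
    independent of atom input order.  Multi-fragment molecules are handled by
    enumerating within fragments only (a warning is emitted); single-heavy-atom
    molecules yield an empty multiset.
    """
    mol = _as_mol(molecule)
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    counts: Counter[PairCode] = Counter()
    if len(heavy) < 2:
        return counts
    codes = {i: atom_code(mol, i) for i in heavy}
    dmat = Chem.GetDistanceMatrix(mol)
    crossed_fragments = False
    for a_pos, i in enumerate(heavy):
        for j in heavy[a_pos + 1 :]:
            d = dmat[i, j]
            if d >= _NO_PATH:
                crossed_fragments = True
                continue
            if 1 <= d <= max_distance:
                counts[PairCode.make(codes[i], codes[j], int(d))] += 1
    if crossed_fragments:
        warnings.warn(
            "multi-fragment molecule: pairs enumerated within fragments only",
            stacklevel=2,
        )
    return counts
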