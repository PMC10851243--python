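"""Aggregate per-pair quantum-property statistics from a reference database.

The reference database is a table of small organic molecules (SMILES) with
11 quantum-chemical properties per molecule, following the QM9 schema:
dipole moment (Debye), isotropic polarizability (a.u.), HOMO and LUMO
energies and their gap (Hartree), zero-point vibrational energy, internal
energies at 0 K and 298.15 K, enthalpy and free energy at 298.15 K
(Hartree), and heat capacity at 298.15 K (cal/(mol K)).

For every atom pair observed in the database the lookup stores three
aggregates over the molecules containing that pair:

* the arithmetic mean of the molecules' property vectors, each molecule's
  value first divided by the number of occurrences of the pair in that
  molecule (one contribution per molecule, not per occurrence);
* per-property relative-frequency histograms of those same
  occurrence-divided contributions over ``n_bins`` equal-width bins
  spanning the pair's observed range (bin edges are stored);
* the support, i.e. the number of contributing molecules.

Only pairs over C, O, N, F, S, Cl and Br enter the lookup; reference
molecules containing other heavy elements are skipped, which later defines
the applicability domain of the descriptors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .pairs import DEFAULT_MAX_DISTANCE, PairCode, enumerate_pairs, mol_from_smiles

__all__ = [
    "PROPERTY_NAMES",
    "LOOKUP_ELEMENTS",
    "QuantumRecord",
    "PairStatistics",
    "QAPLookup",
    "read_quantum_database",
    "pair_contributions",
    "build_lookup",
    "save_lookup",
    "load_lookup",
]

logger = logging.getLogger(__name__)

#: The 11 quantum properties, in fixed order.
PROPERTY_NAMES = (
    "dipole_moment",
    "isotropic_polarizability",
    "homo_energy",
    "lumo_energy",
    "homo_lumo_gap",
    "zpve",
    "u0",
    "u298",
    "h298",
    "g298",
    "cv298",
)

N_PROPERTIES = len(PROPERTY_NAMES)

#: QM9-style short column names accepted as aliases in input tables.
COLUMN_ALIASES: Dict[str, str] = {
    "mu": "dipole_moment",
    "alpha": "isotropic_polarizability",
    "homo": "homo_energy",
    "lumo": "lumo_energy",
    "gap": "homo_lumo_gap",
    "cv": "cv298",
}

#: Heavy elements admissible in lookup pairs.
LOOKUP_ELEMENTS = frozenset({"C", "O", "N", "F", "S", "Cl", "Br"})

_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class QuantumRecord:
    """One reference molecule: SMILES plus its 11 quantum properties."""

    smiles: str
    properties: np.ndarray  # shape (11,), order PROPERTY_NAMES

    def __post_init__(self) -> None:
        props = np.asarray(self.properties, dtype=float)
        if props.shape != (N_PROPERTIES,):
            raise ValueError(f"expected {N_PROPERTIES} properties, got shape {props.shape}")
        if not np.all(np.isfinite(props)):
            raise ValueError(f"non-finite property for {self.smiles!r}")
        object.__setattr__(self, "properties", props)


@dataclass(frozen=True)
class PairStatistics:
    """Aggregated statistics of one pair over the reference molecules."""

    mean_properties: np.ndarray  # (11,)
    histograms: np.ndarray  # (11, n_bins) relative frequencies (or counts)
    bin_edges: np.ndarray  # (11, n_bins + 1)
    support: int

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("support must be >= 1")


@dataclass
class QAPLookup:
    """Pair-code keyed table of aggregated quantum-property statistics."""

    entries: Dict[PairCode, PairStatistics]
    max_distance: int = DEFAULT_MAX_DISTANCE
    n_bins: int = 10
    property_names: Sequence[str] = PROPERTY_NAMES
    provenance: Dict[str, object] = field(default_factory=dict)
    pair_order: List[PairCode] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pair_order:
            self.pair_order = sorted(self.entries)
        if sorted(self.pair_order) != sorted(self.entries):
            raise ValueError("pair_order must be a permutation of the entry keys")

    @property
    def n_pairs(self) -> int:
        return len(self.entries)

    def __contains__(self, pair: PairCode) -> bool:
        return pair in self.entries

    def __getitem__(self, pair: PairCode) -> PairStatistics:
        return self.entries[pair]

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "schema_version": _SCHEMA_VERSION,
            "max_distance": self.max_distance,
            "n_bins": self.n_bins,
            "property_names": list(self.property_names),
            "provenance": self.provenance,
            "entries": {
                str(pair): {
                    "mean": self.entries[pair].mean_properties.tolist(),
                    "histograms": self.entries[pair].histograms.tolist(),
                    "bin_edges": self.entries[pair].bin_edges.tolist(),
                    "support": self.entries[pair].support,
                }
                for pair in self.pair_order
            },
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "QAPLookup":
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ValueError(f"corrupted lookup file: {exc}") from exc
        version = doc.get("schema_version")
        if version != _SCHEMA_VERSION:
            raise ValueError(f"unsupported lookup schema version: {version!r}")
        entries: Dict[PairCode, PairStatistics] = {}
        order: List[PairCode] = []
        for key, payload in doc["entries"].items():
            pair = PairCode.from_string(key)
            order.append(pair)
            entries[pair] = PairStatistics(
                mean_properties=np.asarray(payload["mean"], dtype=float),
                histograms=np.asarray(payload["histograms"], dtype=float),
                bin_edges=np.asarray(payload["bin_edges"], dtype=float),
                support=int(payload["support"]),
            )
        return cls(
            entries=entries,
            max_distance=int(doc["max_distance"]),
            n_bins=int(doc["n_bins"]),
            property_names=tuple(doc["property_names"]),
            provenance=dict(doc.get("provenance", {})),
            pair_order=order,
        )

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: Union[str, Path]) -> "QAPLookup":
        return cls.from_json(Path(path).read_text())


def save_lookup(lookup: QAPLookup, path: Union[str, Path]) -> None:
    lookup.save(path)


def load_lookup(path: Union[str, Path]) -> QAPLookup:
    return QAPLookup.load(path)


def read_quantum_database(
    path: Union[str, Path],
    smiles_column: str = "smiles",
    property_columns: Optional[Mapping[str, str]] = None,
) -> List[QuantumRecord]:
    """Read a reference-database CSV into :class:`QuantumRecord` rows.

    ``property_columns`` maps canonical property names to column names; by
    default the canonical names themselves plus the QM9 short aliases
    (mu, alpha, homo, lumo, gap, cv) are accepted.  Rows with unparseable
    SMILES or missing/non-finite properties are dropped with a logged count;
    row order is otherwise preserved.
    """
    table = pd.read_csv(path)
    if table.empty:
        raise ValueError(f"empty reference table: {path}")
    renames = {alias: canonical for alias, canonical in COLUMN_ALIASES.items()
               if alias in table.columns}
    table = table.rename(columns=renames)
    colmap = {name: name for name in PROPERTY_NAMES}
    if property_columns:
        colmap.update(property_columns)
    if smiles_column not in table.columns:
        raise ValueError(f"missing SMILES column {smiles_column!r}")
    missing = [colmap[name] for name in PROPERTY_NAMES if colmap[name] not in table.columns]
    if missing:
        raise ValueError(f"missing property column(s): {', '.join(missing)}")

    records: List[QuantumRecord] = []
    n_dropped = 0
    values = table[[colmap[name] for name in PROPERTY_NAMES]].to_numpy(dtype=float)
    for row_idx, smiles in enumerate(table[smiles_column].astype(str)):
        props = values[row_idx]
        if not np.all(np.isfinite(props)):
            n_dropped += 1
            continue
        try:
            mol_from_smiles(smiles)
        except ValueError:
            n_dropped += 1
            continue
        records.append(QuantumRecord(smiles=smiles, properties=props))
    if n_dropped:
        logger.info("dropped %d malformed row(s) from %s", n_dropped, path)
    return records


def _allowed_elements(smiles: str) -> bool:
    mol = mol_from_smiles(smiles)
    return all(
        a.GetSymbol() in LOOKUP_ELEMENTS for a in mol.GetAtoms() if a.GetAtomicNum() > 1
    )


def pair_contributions(
    record: QuantumRecord, max_distance: int = DEFAULT_MAX_DISTANCE
) -> Dict[PairCode, np.ndarray]:
    """Occurrence-divided property contributions of one reference molecule.

    A pair occurring ``n`` times contributes the molecule's property vector
    divided by ``n`` — exactly one contribution per distinct pair per
    molecule.  A molecule with no pairs yields an empty mapping.
    """
    counts = enumerate_pairs(record.smiles, max_distance=max_distance)
    return {pair: record.properties / n for pair, n in counts.items()}


def _histogram(values: np.ndarray, n_bins: int, relative: bool) -> tuple:
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        # Degenerate range: all mass in the centre bin, edges span value +- 0.5.
        edges = np.linspace(lo - 0.5, hi + 0.5, n_bins + 1)
        hist = np.zeros(n_bins)
        hist[n_bins // 2 - 1 if n_bins % 2 == 0 else n_bins // 2] = float(len(values))
    else:
        hist, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
        hist = hist.astype(float)
    if relative:
        hist = hist / hist.sum()
    return hist, edges


def build_lookup(
    records: Sequence[QuantumRecord],
    max_distance: int = DEFAULT_MAX_DISTANCE,
    n_bins: int = 10,
    relative_histograms: bool = True,
    provenance: Optional[Dict[str, object]] = None,
) -> QAPLookup:
    """Aggregate reference records into a :class:`QAPLookup`.

    Records containing heavy elements outside C/O/N/F/S/Cl/Br are skipped
    with a logged count.  For every pair observed in at least one record the
    mean, per-property histograms and support are computed over that pair's
    occurrence-divided contributions.  The result does not depend on record
    order.
    """
    contributions: Dict[PairCode, List[np.ndarray]] = {}
    n_skipped = 0
    n_used = 0
    for record in records:
        if not _allowed_elements(record.smiles):
            n_skipped += 1
            continue
        n_used += 1
        for pair, value in pair_contributions(record, max_distance=max_distance).items():
            contributions.setdefault(pair, []).append(value)
    if n_skipped:
        logger.info("skipped %d record(s) with elements outside %s",
                    n_skipped, sorted(LOOKUP_ELEMENTS))
    if not contributions:
        raise ValueError("no atom pairs observed in any record")

    entries: Dict[PairCode, PairStatistics] = {}
    for pair in sorted(contributions):
        stack = np.vstack(contributions[pair])  # (support, 11)
        hists = np.empty((N_PROPERTIES, n_bins))
        edges = np.empty((N_PROPERTIES, n_bins + 1))
        for k in range(N_PROPERTIES):
            hists[k], edges[k] = _histogram(stack[:, k], n_bins, relative_histograms)
        entries[pair] = PairStatistics(
            mean_properties=stack.mean(axis=0),
            histograms=hists,
            bin_edges=edges,
            support=stack.shape[0],
        )
    meta: Dict[str, object] = {
        "n_records_used": n_used,
        "n_records_skipped": n_skipped,
        "relative_histograms": relative_histograms,
    }
    if provenance:
        meta.update(provenance)
    return QAPLookup(
        entries=entries, max_distance=max_distance, n_bins=n_bins, provenance=meta
    )
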