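"""Applicability-domain filtering and the three QAP descriptor layouts.

A molecule is inside the applicability domain of a lookup when every atom
pair it contains (up to the lookup's distance cutoff) is present in the
lookup and it has at least one pair.  Molecules outside the domain cannot
be featurized, because their descriptors would require per-pair statistics
the reference database never produced.

Three descriptor layouts are derived from a lookup:

* sumQAP — the sum over the molecule's pairs of the pairs' mean property
  vectors: 11 descriptors;
* hQAP — the sum over pairs of the pairs' concatenated per-property
  histograms: 11 properties x n_bins values (110 with 10 bins);
* spQAP — one 11-value block per pair known to the lookup, filled with the
  pair's mean properties when the molecule contains the pair and zeros
  otherwise: 11 x n_pairs values.

sumQAP and hQAP multiply each pair's block by its occurrence count by
default (making the descriptors additive over disconnected fragments);
spQAP is presence-gated by default.  Both conventions are switchable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .lookup import LOOKUP_ELEMENTS, QAPLookup
from .pairs import MoleculeLike, enumerate_pairs, mol_from_smiles

__all__ = [
    "FeatureMatrix",
    "DomainReport",
    "DomainError",
    "in_domain",
    "filter_domain",
    "featurize_sum",
    "featurize_hist",
    "featurize_sparse",
    "featurize_matrix",
    "variance_filter",
]


class DomainError(ValueError):
    """Raised when a molecule outside the applicability domain is featurized."""


@dataclass
class FeatureMatrix:
    """Dense molecules x descriptors matrix with aligned names."""

    row_ids: List[str]
    feature_names: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.feature_names)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.row_ids)} rows / {len(self.feature_names)} features"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.feature_names)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureMatrix":
        return cls(
            row_ids=[str(i) for i in frame.index],
            feature_names=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
        )


@dataclass
class DomainReport:
    """Accounting of an applicability-domain filtering pass."""

    n_input: int
    n_in_domain: int
    rejected: List[Tuple[str, str]]  # (molecule id, reason)

    def __post_init__(self) -> None:
        if self.n_input != self.n_in_domain + len(self.rejected):
            raise ValueError("report does not account for every input molecule")


def in_domain(molecule: MoleculeLike, lookup: QAPLookup) -> Tuple[bool, Optional[str]]:
    """Decide membership in the lookup's applicability domain.

    Returns ``(True, None)`` when the molecule parses, contains only the
    lookup's legal elements, has at least one pair, and every pair is known
    to the lookup.  Otherwise returns ``(False, reason)`` with reason one of
    ``parse_error``, ``forbidden_element``, ``no_pairs``, ``unknown_pair``.
    """
    try:
        mol = mol_from_smiles(molecule) if isinstance(molecule, str) else molecule
    except ValueError:
        return False, "parse_error"
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() > 1 and atom.GetSymbol() not in LOOKUP_ELEMENTS:
            return False, "forbidden_element"
    counts = enumerate_pairs(mol, max_distance=lookup.max_distance)
    if not counts:
        return False, "no_pairs"
    for pair in counts:
        if pair not in lookup:
            return False, "unknown_pair"
    return True, None


def filter_domain(
    molecules: Sequence[str],
    lookup: QAPLookup,
    ids: Optional[Sequence[str]] = None,
) -> Tuple[List[str], DomainReport]:
    """Split molecules into the in-domain subset and a rejection report.

    The subset preserves input order; every input is accounted for either in
    the subset or in the report's rejection list.  Failures are reported,
    never raised.
    """
    if ids is None:
        ids = [str(i) for i in range(len(molecules))]
    kept: List[str] = []
    rejected: List[Tuple[str, str]] = []
    for mol_id, smiles in zip(ids, molecules):
        ok, reason = in_domain(smiles, lookup)
        if ok:
            kept.append(smiles)
        else:
            rejected.append((str(mol_id), reason))
    return kept, DomainReport(len(molecules), len(kept), rejected)


def _checked_counts(molecule: MoleculeLike, lookup: QAPLookup):
    ok, reason = in_domain(molecule, lookup)
    if not ok:
        raise DomainError(f"molecule outside applicability domain ({reason})")
    return enumerate_pairs(molecule, max_distance=lookup.max_distance)


def featurize_sum(
    molecule: MoleculeLike, lookup: QAPLookup, count_weighted: bool = True
) -> np.ndarray:
    """sumQAP: occurrence-weighted sum of per-pair mean properties (11 values)."""
    counts = _checked_counts(molecule, lookup)
    out = np.zeros(len(lookup.property_names))
    for pair in sorted(counts):  # canonical order: bit-identical across SMILES spellings
        out += (counts[pair] if count_weighted else 1) * lookup[pair].mean_properties
    return out


def featurize_hist(
    molecule: MoleculeLike, lookup: QAPLookup, count_weighted: bool = True
) -> np.ndarray:
    """hQAP: summed per-pair histogram blocks (11 properties x n_bins values)."""
    counts = _checked_counts(molecule, lookup)
    out = np.zeros(len(lookup.property_names) * lookup.n_bins)
    for pair in sorted(counts):
        out += (counts[pair] if count_weighted else 1) * lookup[pair].histograms.ravel()
    return out


def featurize_sparse(
    molecule: MoleculeLike, lookup: QAPLookup, count_weighted: bool = False
) -> np.ndarray:
    """spQAP: one 11-block per lookup pair, zero unless the molecule has it."""
    counts = _checked_counts(molecule, lookup)
    n_props = len(lookup.property_names)
    out = np.zeros(n_props * lookup.n_pairs)
    index = {pair: k for k, pair in enumerate(lookup.pair_order)}
    for pair, n in counts.items():
        k = index[pair]
        out[k * n_props : (k + 1) * n_props] = (
            n if count_weighted else 1
        ) * lookup[pair].mean_properties
    return out


_METHODS = {
    "sum": (featurize_sum, True),
    "hist": (featurize_hist, True),
    "sparse": (featurize_sparse, False),
}


def _feature_names(lookup: QAPLookup, method: str) -> List[str]:
    props = list(lookup.property_names)
    if method == "sum":
        return [f"qap_sum|{p}" for p in props]
    if method == "hist":
        return [f"qap_hist|{p}|bin{k}" for p in props for k in range(lookup.n_bins)]
    return [f"qap|{pair}|{p}" for pair in lookup.pair_order for p in props]


def featurize_matrix(
    molecules: Sequence[str],
    lookup: QAPLookup,
    method: str = "sum",
    ids: Optional[Sequence[str]] = None,
    count_weighted: Optional[bool] = None,
) -> FeatureMatrix:
    """Featurize a batch of in-domain molecules into a :class:`FeatureMatrix`.

    Rows align with input order and feature names are stable across calls
    with the same lookup.  Any out-of-domain molecule aborts the batch with
    an error naming the offending row.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHODS)}")
    func, default_weighted = _METHODS[method]
    weighted = default_weighted if count_weighted is None else count_weighted
    if ids is None:
        ids = [str(i) for i in range(len(molecules))]
    rows = []
    for mol_id, smiles in zip(ids, molecules):
        try:
            rows.append(func(smiles, lookup, count_weighted=weighted))
        except DomainError as exc:
            raise DomainError(f"molecule {mol_id!r}: {exc}") from exc
    names = _feature_names(lookup, method)
    values = np.vstack(rows) if rows else np.empty((0, len(names)))
    return FeatureMatrix(row_ids=[str(i) for i in ids], feature_names=names, values=values)


def variance_filter(matrix: FeatureMatrix, min_std: float = 0.05) -> FeatureMatrix:
    """Dismiss descriptor columns whose population standard deviation is below
    ``min_std`` (strictly less than; a column at exactly the threshold stays).

    Applied once, globally, on the full design matrix before any model
    fitting.  Raises if nothing survives.
    """
    if matrix.values.shape[0] == 0:
        raise ValueError("cannot variance-filter an empty matrix")
    stds = matrix.values.std(axis=0, ddof=0)
    keep = stds >= min_std
    if not keep.any():
        raise ValueError("variance filter removed every feature")
    return FeatureMatrix(
        row_ids=list(matrix.row_ids),
        feature_names=[n for n, k in zip(matrix.feature_names, keep) if k],
        values=matrix.values[:, keep],
    )
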