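"""Synthetic reference databases and benchmark tasks with known ground truth.

The generator emulates the schema of a quantum-property reference database
(small organics over C/N/O/F/S/Cl/Br with 11 continuous properties per
molecule) so that the lookup builder, the featurizers and the benchmark
harness are all testable without any external download.

Molecules are grown by seeded random attachment with single bonds and an
optional single ring, which keeps valence handling trivial.  Each of the 11
properties of a molecule is generated additively over its atom pairs: every
pair code carries an 11-component latent weight vector (a deterministic
function of the generator seed and the pair identity), the molecule's
property is the occurrence-weighted sum of its pairs' weights plus Gaussian
noise.  Additivity makes sumQAP the correct sufficient feature for the
derived modeling tasks, so descriptor recovery is a provable property of
the pipeline rather than an empirical hope.  The values are not physically
realistic and are not meant to be.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem

from .featurize import featurize_matrix
from .lookup import N_PROPERTIES, QuantumRecord, build_lookup
from .pairs import DEFAULT_MAX_DISTANCE, PairCode, enumerate_pairs

__all__ = [
    "SyntheticSpec",
    "sample_molecules",
    "latent_weights_for",
    "generate_quantum_db",
    "generate_task",
]

_VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1, "S": 2, "Cl": 1, "Br": 1}

#: Default element abundances, weighted toward carbon the way small organic
#: reference sets are (C-rich backbones, occasional heteroatoms and halogens).
_ELEMENT_WEIGHTS = {
    "C": 0.60, "N": 0.12, "O": 0.12, "F": 0.04, "S": 0.06, "Cl": 0.03, "Br": 0.03,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic reference database.

    Molecules are drawn with ``min_heavy_atoms``..``max_heavy_atoms`` heavy
    atoms (by default the top three sizes below the cap, mirroring
    enumerated reference sets where most molecules sit at the size limit)
    and with element abundances weighted toward carbon.
    """

    n_molecules: int = 100
    seed: int = 0
    element_pool: Tuple[str, ...] = ("C", "N", "O", "F", "S", "Cl", "Br")
    max_heavy_atoms: int = 9
    min_heavy_atoms: Optional[int] = None
    property_noise_sd: float = 0.1
    ring_probability: float = 0.3
    element_weights: Optional[Dict[str, float]] = field(default=None, hash=False)
    latent_weights: Optional[Dict[PairCode, np.ndarray]] = field(default=None, hash=False)

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("need n_molecules >= 1")
        if not self.element_pool:
            raise ValueError("element_pool must be non-empty")
        unknown = set(self.element_pool) - set(_VALENCE)
        if unknown:
            raise ValueError(f"unsupported element(s): {sorted(unknown)}")
        if self.property_noise_sd < 0:
            raise ValueError("property_noise_sd must be >= 0")
        if self.min_heavy_atoms is None:
            object.__setattr__(
                self, "min_heavy_atoms", max(2, self.max_heavy_atoms - 2)
            )
        if not 2 <= self.min_heavy_atoms <= self.max_heavy_atoms:
            raise ValueError("need 2 <= min_heavy_atoms <= max_heavy_atoms")


def _element_probs(spec: SyntheticSpec, elements: Sequence[str]) -> np.ndarray:
    weights = spec.element_weights or _ELEMENT_WEIGHTS
    probs = np.array([weights.get(e, 0.05) for e in elements], dtype=float)
    return probs / probs.sum()


def _grow_molecule(rng: np.random.Generator, spec: SyntheticSpec) -> Optional[str]:
    n_heavy = int(rng.integers(spec.min_heavy_atoms, spec.max_heavy_atoms + 1))
    pool = list(spec.element_pool)
    # Monovalent-only pools can still form two-atom molecules.
    growers = [e for e in pool if _VALENCE[e] >= 2] or pool

    mol = Chem.RWMol()
    first = str(rng.choice(growers, p=_element_probs(spec, growers)))
    mol.AddAtom(Chem.Atom(first))
    free = {0: _VALENCE[first]}
    pool_probs = _element_probs(spec, pool)
    for _ in range(n_heavy - 1):
        anchors = [i for i, v in free.items() if v > 0]
        if not anchors:
            break
        anchor = int(anchors[rng.integers(len(anchors))])
        element = str(rng.choice(pool, p=pool_probs))
        idx = mol.AddAtom(Chem.Atom(element))
        mol.AddBond(anchor, idx, Chem.BondType.SINGLE)
        free[anchor] -= 1
        free[idx] = _VALENCE[element] - 1
    if mol.GetNumAtoms() < 2:
        return None
    # Close at most one ring between two free-valence atoms >= 2 bonds apart.
    if rng.random() < spec.ring_probability:
        dmat = Chem.GetDistanceMatrix(mol.GetMol())
        candidates = [
            (i, j)
            for i in free
            for j in free
            if i < j and free[i] > 0 and free[j] > 0 and dmat[i, j] >= 2
        ]
        if candidates:
            i, j = candidates[rng.integers(len(candidates))]
            mol.AddBond(int(i), int(j), Chem.BondType.SINGLE)
    out = mol.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return Chem.MolToSmiles(out)


def sample_molecules(spec: SyntheticSpec) -> List[str]:
    """Draw ``n_molecules`` valence-legal SMILES, deterministically per seed."""
    rng = np.random.default_rng(spec.seed)
    out: List[str] = []
    while len(out) < spec.n_molecules:
        smiles = _grow_molecule(rng, spec)
        if smiles is not None:
            out.append(smiles)
    return out


def latent_weights_for(pair: PairCode, seed: int) -> np.ndarray:
    """The 11 latent property weights of a pair: a pure function of (seed, pair)."""
    digest = hashlib.sha256(f"{seed}|{pair}".encode()).digest()
    sub_seed = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(sub_seed).standard_normal(N_PROPERTIES)


def generate_quantum_db(
    spec: SyntheticSpec, molecules: Optional[Sequence[str]] = None
) -> List[QuantumRecord]:
    """Generate reference records whose properties are additive over pairs.

    Each property is the occurrence-weighted sum of the molecule's pairs'
    latent weights plus N(0, property_noise_sd) noise.  Custom weights can
    be supplied via ``spec.latent_weights`` (missing pairs fall back to the
    seeded defaults).
    """
    if molecules is None:
        molecules = sample_molecules(spec)
    rng = np.random.default_rng(spec.seed + 1)
    records: List[QuantumRecord] = []
    for smiles in molecules:
        props = np.zeros(N_PROPERTIES)
        for pair, count in enumerate_pairs(smiles).items():
            if spec.latent_weights is not None and pair in spec.latent_weights:
                weights = np.asarray(spec.latent_weights[pair], dtype=float)
            else:
                weights = latent_weights_for(pair, spec.seed)
            props += count * weights
        if spec.property_noise_sd > 0:
            props = props + rng.normal(0.0, spec.property_noise_sd, N_PROPERTIES)
        records.append(QuantumRecord(smiles=smiles, properties=props))
    return records


def generate_task(
    records: Sequence[QuantumRecord],
    task: str = "regression",
    seed: int = 0,
    noise_sd: float = 0.2,
    imbalance_ratio: float = 1 / 12,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    n_molecules: Optional[int] = None,
    n_active_properties: int = 2,
) -> Tuple[List[str], np.ndarray]:
    """Derive a modeling task with known ground truth from reference records.

    A lookup is built from all records (the reference database is typically
    much larger than any one modeling set) and the first ``n_molecules``
    molecules form the task; each is featurized as sumQAP.  The latent score
    is a seeded linear combination of ``n_active_properties`` of the
    standardized features — mirroring experimental endpoints that are
    governed by a small number of underlying quantum properties rather than
    all of them at once.  Regression targets add Gaussian noise whose
    standard deviation is ``noise_sd`` times the signal's (so the
    signal-to-noise ratio is 1/noise_sd).  Classification thresholds the
    score at the quantile that yields the requested minority:majority ratio
    (class 1 = minority); the achieved ratio must land within +-10%.
    """
    if not records:
        raise ValueError("need at least one record")
    if task not in ("regression", "classification"):
        raise ValueError(f"unknown task {task!r}")
    lookup = build_lookup(records, max_distance=max_distance)
    molecules = [r.smiles for r in records]
    if n_molecules is not None:
        molecules = molecules[:n_molecules]
    matrix = featurize_matrix(molecules, lookup, method="sum")
    X = matrix.values
    scale = X.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    Xz = (X - X.mean(axis=0)) / scale

    rng = np.random.default_rng(seed)
    n_active = min(max(1, n_active_properties), Xz.shape[1])
    beta = np.zeros(Xz.shape[1])
    active = rng.choice(Xz.shape[1], size=n_active, replace=False)
    beta[active] = rng.standard_normal(n_active)
    score = Xz @ beta
    if task == "regression":
        y = score.copy()
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd * score.std(ddof=0), score.size)
        return molecules, y
    minority_fraction = imbalance_ratio / (1.0 + imbalance_ratio)
    threshold = np.quantile(score, 1.0 - minority_fraction)
    y = (score > threshold).astype(int)
    achieved = y.sum() / max(1, (y == 0).sum())
    if not (0.9 * imbalance_ratio <= achieved <= 1.1 * imbalance_ratio):
        raise ValueError(
            f"imbalance {achieved:.4f} unattainable within 10% of {imbalance_ratio:.4f} "
            f"for n={len(records)} (ties in the score?)"
        )
    return molecules, y
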