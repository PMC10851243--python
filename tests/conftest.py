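import numpy as np
import pytest

from quantumpairs import (
    QuantumRecord,
    SyntheticSpec,
    build_lookup,
    generate_quantum_db,
)


def make_record(smiles: str, dipole: float, base: float = 1.0) -> QuantumRecord:
    """A record with a chosen dipole moment and distinct remaining properties."""
    props = np.full(11, base) + 0.1 * np.arange(11)
    props[0] = dipole
    return QuantumRecord(smiles=smiles, properties=props)


@pytest.fixture(scope="session")
def alkane_records():
    """Hand-checkable fixture: ethane, propane, butane with known dipoles."""
    return [
        make_record("CC", 6.0, base=1.0),
        make_record("CCC", 6.0, base=2.0),
        make_record("CCCC", 12.0, base=3.0),
    ]


@pytest.fixture(scope="session")
def alkane_lookup(alkane_records):
    return build_lookup(alkane_records)


@pytest.fixture(scope="session")
def synthetic_spec():
    return SyntheticSpec(n_molecules=60, seed=20240126, property_noise_sd=0.05)


@pytest.fixture(scope="session")
def synthetic_records(synthetic_spec):
    return generate_quantum_db(synthetic_spec)


@pytest.fixture(scope="session")
def synthetic_lookup(synthetic_records):
    return build_lookup(synthetic_records)
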