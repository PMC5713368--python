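import numpy as np
import pytest

from seqdesc.alphabet import SequenceType, TypeRegistry
from seqdesc.properties import PropertyRegistry, PropertyTable, normalize_table


@pytest.fixture
def rng():
    return np.random.default_rng(20251701)


@pytest.fixture
def dna():
    return SequenceType("DNA", tuple("ACGT"), {"A": "T", "T": "A", "C": "G", "G": "C"})


@pytest.fixture
def prot():
    return SequenceType("PROT", tuple("ACDEFGHIKLMNPQRSTVWY"))


@pytest.fixture
def ab_type():
    """Minimal two-letter alphabet used by most worked examples."""
    return SequenceType("AB", ("A", "B"), {"A": "B", "B": "A"})


def make_table(name, seqtype, values, tuple_size=1, normalized=True):
    table = PropertyTable(
        name=name, seqtype=seqtype.name, tuple_size=tuple_size,
        raw={k: float(v) for k, v in values.items()},
    )
    return normalize_table(table) if normalized else table


@pytest.fixture
def ab_h1(ab_type):
    """{A: -1, B: +1} after normalization (raw 1, 3)."""
    return make_table("h1", ab_type, {"A": 1.0, "B": 3.0})


@pytest.fixture
def ab_h2(ab_type):
    """{A: +1, B: -1} after normalization (raw 3, 1)."""
    return make_table("h2", ab_type, {"A": 3.0, "B": 1.0})
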