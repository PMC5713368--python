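"""Synthetic FASTA and toy property-table generators.

All test fixtures in this package are generated programmatically: random
sequences over any registered alphabet, FASTA text in the five database
header dialects, toy property tables with random (non-constant) values,
and a mixed-quality FASTA with a controlled number of invalid-letter and
too-short records for exercising the fault policy.

Sequences are drawn uniformly over the alphabet, which emulates the only
aspect of real data the descriptor engine is sensitive to — letter order
and composition — and none of the biological structure (codon bias,
domain architecture, repeat content) real sequences carry.
"""

from __future__ import annotations

import numpy as np

from .alphabet import SequenceRecord, SequenceType
from .properties import PropertyTable, normalize_table

__all__ = [
    "random_sequences",
    "random_records",
    "records_to_fasta",
    "dialect_headers",
    "toy_property_table",
    "fault_fixture_fasta",
]


def random_sequences(
    seqtype: SequenceType,
    n: int,
    rng: np.random.Generator,
    length_range: tuple[int, int] = (5, 50),
) -> list[str]:
    """``n`` uniform-random sequences with lengths in ``length_range``."""
    lo, hi = length_range
    letters = np.array(list(seqtype.alphabet))
    out = []
    for _ in range(n):
        length = int(rng.integers(lo, hi + 1))
        out.append("".join(letters[rng.integers(0, seqtype.size, length)]))
    return out


def random_records(
    seqtype: SequenceType,
    n: int,
    rng: np.random.Generator,
    length_range: tuple[int, int] = (5, 50),
    prefix: str = "seq",
) -> list[SequenceRecord]:
    return [
        SequenceRecord(id=f"{prefix}{i + 1}", letters=s)
        for i, s in enumerate(random_sequences(seqtype, n, rng, length_range))
    ]


def records_to_fasta(records, width: int | None = 60) -> str:
    """Multi-line FASTA text (``width=None`` for single-line records)."""
    chunks = []
    for rec in records:
        header = f">{rec.id} {rec.comment}".rstrip()
        chunks.append(header)
        if width:
            chunks.extend(rec.letters[i : i + width] for i in range(0, len(rec.letters), width))
        else:
            chunks.append(rec.letters)
    return "\n".join(chunks) + "\n"


def dialect_headers() -> dict[str, str]:
    """One synthetic header line per recognized database dialect."""
    return {
        "UNIPROT": ">sp|P12345|TEST_HUMAN synthetic uniprot entry",
        "GENBANK": ">U49845.1 synthetic genbank entry",
        "EMBL": ">ENA|AB000001|AB000001.1 synthetic ena entry",
        "DDBJ": ">gi|2765658|dbj|AB000263|AB000263.1 synthetic ddbj entry",
        "REFSEQ": ">NM_000546.6 synthetic refseq entry",
    }


def toy_property_table(
    seqtype: SequenceType,
    tuple_size: int,
    rng: np.random.Generator,
    name: str = "toy",
    normalized: bool = True,
) -> PropertyTable:
    """A random non-constant property over all |A|^n tuples."""
    import itertools

    tuples = ["".join(p) for p in itertools.product(seqtype.alphabet, repeat=tuple_size)]
    while True:
        values = rng.normal(0.0, 1.0, len(tuples))
        if values.std() > 1e-6:
            break
    table = PropertyTable(
        name=name,
        seqtype=seqtype.name,
        tuple_size=tuple_size,
        raw={t: float(v) for t, v in zip(tuples, values)},
    )
    return normalize_table(table) if normalized else table


def fault_fixture_fasta(
    seqtype: SequenceType,
    rng: np.random.Generator,
    n_valid: int = 7,
    n_invalid_letter: int = 2,
    n_too_short: int = 1,
    valid_length: int = 30,
    short_length: int = 1,
) -> str:
    """A FASTA with a known number of clean, bad-letter and short records.

    Record ids are ``ok1..``, ``bad1..`` (one letter outside the alphabet)
    and ``short1..`` (length ``short_length``, too short for any mode
    needing more positions); record order is shuffled deterministically by
    ``rng``.
    """
    letters = np.array(list(seqtype.alphabet))
    records = []
    for i in range(n_valid):
        seq = "".join(letters[rng.integers(0, seqtype.size, valid_length)])
        records.append(SequenceRecord(id=f"ok{i + 1}", letters=seq))
    bad_letter = "1" if seqtype.case_fold else "?"
    bad_letter = "?"  # never strippable, never in any alphabet
    for i in range(n_invalid_letter):
        seq = "".join(letters[rng.integers(0, seqtype.size, valid_length)])
        pos = int(rng.integers(0, valid_length))
        records.append(
            SequenceRecord(id=f"bad{i + 1}", letters=seq[:pos] + bad_letter + seq[pos + 1 :])
        )
    for i in range(n_too_short):
        seq = "".join(letters[rng.integers(0, seqtype.size, short_length)])
        records.append(SequenceRecord(id=f"short{i + 1}", letters=seq))
    order = rng.permutation(len(records))
    return records_to_fasta([records[i] for i in order])
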