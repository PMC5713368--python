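"""Physicochemical property tables and pre-computed pair correlations.

A :class:`PropertyTable` assigns a real value to every *n*-tuple of an
alphabet (n=1 for amino-acid or nucleotide properties, n=2 for
dinucleotides, n=3 for trinucleotides).  Before use in correlation
descriptors the raw values H⁰ are standardized to zero mean and unit
*population* standard deviation over all |A|ⁿ tuples:

    H(a) = (H⁰(a) − mean) / pop_std

The speed mechanism of the engine is :class:`PairCorrelationTable`: for a
set of Γ normalized properties it pre-computes, over all tuple pairs
(a, b),

    Θ(a, b) = (1/Γ) Σ_k [H_k(a) − H_k(b)]²      (averaged squared difference)
    Π_v(a, b) = P_v(a) · P_v(b)                  (per-property products)

so every descriptor kernel is a table lookup per position pair instead of
re-evaluating property arithmetic.  Tuple index order along each matrix
axis is lexicographic by alphabet index (row-major over positions), e.g.
dinucleotide index = 4·idx(first) + idx(second) for DNA.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

from .alphabet import DefinitionError, SequenceError, SequenceType

__all__ = [
    "PropertyError",
    "NormalizationError",
    "PropertyTable",
    "PairCorrelationTable",
    "load_property_table",
    "parse_property_table",
    "normalize_table",
    "build_pair_tables",
    "tuple_indices",
    "PropertyRegistry",
    "BUILTIN_PROPERTY_FILES",
    "DEFAULT_PROPERTY_SETS",
]


class PropertyError(SequenceError):
    """Malformed or incomplete property table."""


class NormalizationError(PropertyError):
    """Property table cannot be standardized (zero variance)."""


@dataclass
class PropertyTable:
    """A named physicochemical property over n-tuples of an alphabet."""

    name: str
    seqtype: str
    tuple_size: int
    raw: dict[str, float]
    normalized: dict[str, float] | None = None

    def tuples(self, seqtype: SequenceType) -> list[str]:
        """All |A|^n tuples in lexicographic (alphabet-index) order."""
        return [
            "".join(p) for p in itertools.product(seqtype.alphabet, repeat=self.tuple_size)
        ]

    def values_array(self, seqtype: SequenceType, normalized: bool = True) -> np.ndarray:
        """Values as a vector over tuple indices (lexicographic order)."""
        source = self.normalized if normalized else self.raw
        if source is None:
            raise PropertyError(f"property {self.name!r} is not normalized")
        return np.array([source[t] for t in self.tuples(seqtype)], dtype=float)


def parse_property_table(text: str, seqtype: SequenceType) -> PropertyTable:
    """Parse the plain-text property format.

    Header lines ``#name:``, ``#seqtype:``, ``#tuple:``; body lines
    ``TUPLE value``; other ``#`` lines are comments.  The table must cover
    every tuple exactly once.
    """
    name = None
    declared_type = None
    tuple_size = None
    raw: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.lower().startswith("name:"):
                name = body[5:].strip()
            elif body.lower().startswith("seqtype:"):
                declared_type = body[8:].strip()
            elif body.lower().startswith("tuple:"):
                tuple_size = int(body[6:].strip())
            continue
        parts = line.split()
        if len(parts) != 2:
            raise PropertyError(f"line {lineno}: expected 'TUPLE value', got {line!r}")
        tup, val = parts
        if seqtype.case_fold:
            tup = tup.upper()
        try:
            value = float(val)
        except ValueError:
            raise PropertyError(f"line {lineno}: bad value {val!r}") from None
        if tup in raw:
            raise PropertyError(f"line {lineno}: duplicate tuple {tup}")
        raw[tup] = value

    if name is None:
        raise PropertyError("missing '#name:' header")
    if tuple_size is None:
        tuple_size = len(next(iter(raw), "")) or 1
    if declared_type is not None and declared_type != seqtype.name:
        raise PropertyError(
            f"property {name!r} declares seqtype {declared_type!r}, expected {seqtype.name!r}"
        )

    alphabet = set(seqtype.alphabet)
    for tup in raw:
        if len(tup) != tuple_size:
            raise PropertyError(f"tuple {tup!r} is not of length {tuple_size}")
        bad = [ch for ch in tup if ch not in alphabet]
        if bad:
            raise PropertyError(
                f"tuple {tup!r}: letter {bad[0]!r} outside alphabet of {seqtype.name}"
            )
    expected = [
        "".join(p) for p in itertools.product(seqtype.alphabet, repeat=tuple_size)
    ]
    missing = [t for t in expected if t not in raw]
    if missing:
        raise PropertyError(
            f"property {name!r}: missing {' '.join(missing[:5])}"
            + ("..." if len(missing) > 5 else "")
        )
    return PropertyTable(name=name, seqtype=seqtype.name, tuple_size=tuple_size, raw=raw)


def load_property_table(
    source: str | Path | TextIO, seqtype: SequenceType
) -> PropertyTable:
    """Load a property table from a file path or open handle."""
    if hasattr(source, "read"):
        text = source.read()  # type: ignore[union-attr]
    else:
        text = Path(source).read_text()
    return parse_property_table(text, seqtype)


def normalize_table(table: PropertyTable) -> PropertyTable:
    """Standardize to zero mean and unit population standard deviation.

    Idempotent on already-normal tables (to within 1e-9).  A constant raw
    table has no scale and raises :class:`NormalizationError`.
    """
    values = np.array(list(table.raw.values()), dtype=float)
    mean = values.mean()
    std = values.std(ddof=0)  # population denominator |A|^n
    if std < 1e-12:
        raise NormalizationError(f"property {table.name!r} has zero variance")
    normalized = {t: (v - mean) / std for t, v in table.raw.items()}
    return PropertyTable(
        name=table.name,
        seqtype=table.seqtype,
        tuple_size=table.tuple_size,
        raw=dict(table.raw),
        normalized=normalized,
    )


@dataclass
class PairCorrelationTable:
    """Pre-computed Θ and Π_v matrices over all tuple-index pairs.

    ``theta`` is symmetric with zero diagonal and non-negative entries;
    ``products[v]`` is the outer product of property v with itself.
    ``combine`` records whether Θ averages over properties (classic) or
    sums them.
    """

    seqtype: str
    tuple_size: int
    property_names: tuple[str, ...]
    theta: np.ndarray
    products: np.ndarray  # shape (Γ, S, S)
    combine: str = "average"

    @property
    def n_properties(self) -> int:
        return len(self.property_names)


def build_pair_tables(
    properties: Sequence[PropertyTable],
    seqtype: SequenceType,
    combine: str = "average",
) -> PairCorrelationTable:
    """Pre-compute Θ and Π_v for a property set (same seqtype and n).

    All tables must already be normalized.  ``combine="average"`` divides
    the squared-difference sum by Γ (the classic convention);
    ``combine="sum"`` leaves the plain sum for user-defined modes.
    """
    if not properties:
        raise DefinitionError("at least one property table is required")
    sizes = {p.tuple_size for p in properties}
    if len(sizes) > 1:
        raise DefinitionError(f"mixed tuple sizes {sorted(sizes)} in property set")
    types = {p.seqtype for p in properties}
    if len(types) > 1 or properties[0].seqtype != seqtype.name:
        raise DefinitionError("all properties must share the target sequence type")
    if combine not in ("average", "sum"):
        raise DefinitionError(f"combine must be 'average' or 'sum', got {combine!r}")

    n = properties[0].tuple_size
    vals = np.stack([p.values_array(seqtype) for p in properties])  # (Γ, S)
    diff = vals[:, :, None] - vals[:, None, :]
    theta = (diff**2).sum(axis=0)
    if combine == "average":
        theta = theta / len(properties)
    products = vals[:, :, None] * vals[:, None, :]
    return PairCorrelationTable(
        seqtype=seqtype.name,
        tuple_size=n,
        property_names=tuple(p.name for p in properties),
        theta=theta,
        products=products,
        combine=combine,
    )


def tuple_indices(indices: np.ndarray, n: int, alphabet_size: int) -> np.ndarray:
    """Tuple index at each of the L−n+1 positions (lexicographic encoding)."""
    L = indices.shape[0]
    if L < n:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(L - n + 1, dtype=np.int64)
    for offset in range(n):
        out = out * alphabet_size + indices[offset : L - n + 1 + offset]
    return out


# ---------------------------------------------------------------------------
# Built-in property tables (bundled data files)
# ---------------------------------------------------------------------------

#: name → (data file, seqtype). The protein trio carries the classic
#: published values used by the original pseudo-composition formulation
#: (hydrophobicity, hydrophilicity, side-chain mass). The nucleotide
#: helical-parameter files are synthetic representative stand-ins (see the
#: file headers); supply your own tables for publication-grade work.
BUILTIN_PROPERTY_FILES: dict[str, tuple[str, str]] = {
    "hydrophobicity": ("prot_hydrophobicity.prop", "PROT"),
    "hydrophilicity": ("prot_hydrophilicity.prop", "PROT"),
    "side-chain-mass": ("prot_sidechain_mass.prop", "PROT"),
    "dna-twist": ("dna_twist_synthetic.prop", "DNA"),
    "dna-tilt": ("dna_tilt_synthetic.prop", "DNA"),
    "dna-roll": ("dna_roll_synthetic.prop", "DNA"),
    "dna-shift": ("dna_shift_synthetic.prop", "DNA"),
    "dna-slide": ("dna_slide_synthetic.prop", "DNA"),
    "dna-rise": ("dna_rise_synthetic.prop", "DNA"),
    "dna-tri-bend": ("dna_tri_bend_synthetic.prop", "DNA"),
    "dna-tri-roll": ("dna_tri_roll_synthetic.prop", "DNA"),
    "rna-twist": ("rna_twist_synthetic.prop", "RNA"),
    "rna-tilt": ("rna_tilt_synthetic.prop", "RNA"),
    "rna-roll": ("rna_roll_synthetic.prop", "RNA"),
    "rna-shift": ("rna_shift_synthetic.prop", "RNA"),
    "rna-slide": ("rna_slide_synthetic.prop", "RNA"),
    "rna-rise": ("rna_rise_synthetic.prop", "RNA"),
}

#: Default property sets per (seqtype, tuple_size) used by built-in modes.
DEFAULT_PROPERTY_SETS: dict[tuple[str, int], tuple[str, ...]] = {
    ("PROT", 1): ("hydrophobicity", "hydrophilicity", "side-chain-mass"),
    ("DNA", 2): (
        "dna-twist",
        "dna-tilt",
        "dna-roll",
        "dna-shift",
        "dna-slide",
        "dna-rise",
    ),
    ("DNA", 3): ("dna-tri-bend", "dna-tri-roll"),
    ("RNA", 2): (
        "rna-twist",
        "rna-tilt",
        "rna-roll",
        "rna-shift",
        "rna-slide",
        "rna-rise",
    ),
}


class PropertyRegistry:
    """Named property lookup: bundled tables plus user registrations.

    Built-in tables are loaded (and normalized) lazily on first access.
    """

    def __init__(self, seqtype_registry=None):
        from .alphabet import SEQTYPES

        self._seqtypes = seqtype_registry or SEQTYPES
        self._tables: dict[str, PropertyTable] = {}

    def register(self, table: PropertyTable) -> PropertyTable:
        if table.name in self._tables or table.name in BUILTIN_PROPERTY_FILES:
            raise DefinitionError(f"property {table.name!r} already registered")
        if table.normalized is None:
            table = normalize_table(table)
        self._tables[table.name] = table
        return table

    def unregister(self, name: str) -> None:
        self._tables.pop(name, None)

    def get(self, name: str) -> PropertyTable:
        if name in self._tables:
            return self._tables[name]
        if name in BUILTIN_PROPERTY_FILES:
            fname, type_name = BUILTIN_PROPERTY_FILES[name]
            text = resources.files("seqdesc.data").joinpath(fname).read_text()
            table = parse_property_table(text, self._seqtypes.get(type_name))
            table = normalize_table(table)
            self._tables[name] = table
            return table
        raise DefinitionError(f"unknown property {name!r}")

    def get_set(self, names: Iterable[str]) -> list[PropertyTable]:
        return [self.get(n) for n in names]

    def default_set(self, seqtype: str, tuple_size: int) -> tuple[str, ...]:
        try:
            return DEFAULT_PROPERTY_SETS[(seqtype, tuple_size)]
        except KeyError:
            raise DefinitionError(
                f"no built-in property set for seqtype {seqtype!r} with "
                f"tuple size {tuple_size}; pass property names explicitly"
            ) from None

    def names(self) -> list[str]:
        return sorted(set(self._tables) | set(BUILTIN_PROPERTY_FILES))
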