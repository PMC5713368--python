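"""Sequence alphabets, internal index encoding, and the data-fault policy.

A :class:`SequenceType` is a named ordered alphabet with an optional
complement map.  Sequences are converted once into arrays of 0-based
alphabet indices (:class:`IndexArray`); every descriptor kernel operates on
those indices and looks numeric quantities up in tables pre-computed per
alphabet, never per sequence.

Formula position subscripts in the descriptor literature are 1-based
(residue ``R_1 .. R_L``); internal indices here are 0-based.  Fault
messages report 1-based positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SequenceError",
    "DefinitionError",
    "ParseError",
    "DataFault",
    "ProcessingAborted",
    "SequenceType",
    "SequenceRecord",
    "IndexArray",
    "FaultPolicy",
    "TypeRegistry",
    "define_seqtype",
    "get_seqtype",
    "load_seqtype_file",
    "builtin_seqtypes",
    "encode_sequence",
    "DB_TAGS",
]

# Source-database tags for FASTA records.
DB_TAGS = ("UNIPROT", "GENBANK", "EMBL", "DDBJ", "REFSEQ", "UNKNOWN")

_STRIP_RE = re.compile(r"[\s\d]+")


class SequenceError(Exception):
    """Base class for all errors raised by this package."""


class DefinitionError(SequenceError):
    """Invalid definition of a sequence type, property, or mode."""


class ParseError(SequenceError):
    """Structurally invalid input file (not a per-record data fault)."""


class DataFault(SequenceError):
    """A per-record problem (non-standard letter, insufficient length).

    Data faults are routed through a :class:`FaultPolicy`: under SKIP the
    record is excluded and reported, under ABORT all processing stops.
    """

    def __init__(self, seq_id: str, reason: str):
        super().__init__(f"{seq_id}: {reason}")
        self.seq_id = seq_id
        self.reason = reason


class ProcessingAborted(SequenceError):
    """Raised when a data fault occurs under the ABORT policy."""

    def __init__(self, fault: DataFault):
        super().__init__(f"aborted on data fault — {fault}")
        self.fault = fault


@dataclass(frozen=True)
class SequenceType:
    """A named alphabet with letter→index mapping and optional complements.

    Parameters
    ----------
    name:
        Short identifier, unique within a registry.
    alphabet:
        Ordered distinct single-letter symbols; the internal index of a
        letter is its 0-based position in this ordering.
    complement_map:
        Optional total bijection on the alphabet (required by
        reverse-complement modes).  It need not be an involution.
    case_fold:
        Fold input letters to upper case before lookup (default).  Disable
        for alphabets where case is semantic.
    """

    name: str
    alphabet: tuple[str, ...]
    complement_map: Mapping[str, str] | None = None
    case_fold: bool = True
    _index: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        letters = tuple(self.alphabet)
        if not letters:
            raise DefinitionError(f"sequence type {self.name!r}: empty alphabet")
        for let in letters:
            if len(let) != 1:
                raise DefinitionError(
                    f"sequence type {self.name!r}: symbol {let!r} is not a single letter"
                )
        if len(set(letters)) != len(letters):
            raise DefinitionError(f"sequence type {self.name!r}: duplicate letter in alphabet")
        object.__setattr__(self, "alphabet", letters)
        object.__setattr__(self, "_index", {let: i for i, let in enumerate(letters)})
        if self.complement_map is not None:
            cmap = dict(self.complement_map)
            extra = set(cmap) - set(letters) | set(cmap.values()) - set(letters)
            if extra:
                raise DefinitionError(
                    f"sequence type {self.name!r}: complement letters {sorted(extra)} "
                    "outside the alphabet"
                )
            if set(cmap) != set(letters):
                raise DefinitionError(
                    f"sequence type {self.name!r}: complement map must be total on the alphabet"
                )
            # Injectivity is deliberately not required: a modified letter
            # (e.g. methyl-C) legitimately shares its complement with the
            # unmodified one, so the map is a total function, not
            # necessarily a bijection or involution.
            object.__setattr__(self, "complement_map", cmap)

    @property
    def size(self) -> int:
        """Alphabet size |A|."""
        return len(self.alphabet)

    def index_of(self, letter: str) -> int:
        return self._index[letter]

    def complement_indices(self) -> np.ndarray:
        """Complement map as an index permutation (requires complement_map)."""
        if self.complement_map is None:
            raise DefinitionError(
                f"sequence type {self.name!r} has no complement map"
            )
        return np.array(
            [self._index[self.complement_map[let]] for let in self.alphabet], dtype=np.int64
        )

    def clean(self, letters: str) -> str:
        """Strip whitespace/digits and apply case folding."""
        text = _STRIP_RE.sub("", letters)
        return text.upper() if self.case_fold else text

    def encode(self, seq_id: str, letters: str) -> "IndexArray":
        """Convert raw letters to internal indices.

        Raises
        ------
        DataFault
            On the first letter outside the alphabet (1-based position).
        """
        text = self.clean(letters)
        if not text:
            raise DataFault(seq_id, "empty sequence")
        idx = self._index
        out = np.empty(len(text), dtype=np.int64)
        for i, ch in enumerate(text):
            j = idx.get(ch)
            if j is None:
                raise DataFault(seq_id, f"non-standard letter {ch} at position {i + 1}")
            out[i] = j
        return IndexArray(seq_id=seq_id, indices=out)

    def decode(self, indices: np.ndarray) -> str:
        return "".join(self.alphabet[int(i)] for i in indices)


@dataclass
class SequenceRecord:
    """One FASTA entry: identifier, source database, comment, raw letters."""

    id: str
    letters: str
    db: str = "UNKNOWN"
    comment: str = ""

    def __post_init__(self) -> None:
        if self.db not in DB_TAGS:
            raise DefinitionError(f"unknown database tag {self.db!r}")


@dataclass
class IndexArray:
    """A sequence as 0-based alphabet indices."""

    seq_id: str
    indices: np.ndarray

    @property
    def length(self) -> int:
        return int(self.indices.shape[0])

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.length


class FaultPolicy:
    """What to do with a per-record data fault: skip-and-report or abort.

    Every skipped record generates exactly one report entry
    ``(seq_id, reason)``; ``report_sink``, if given, is called with each
    formatted report line.
    """

    SKIP = "skip"
    ABORT = "abort"

    def __init__(self, on_fault: str = SKIP, report_sink: Callable[[str], None] | None = None):
        if on_fault not in (self.SKIP, self.ABORT):
            raise DefinitionError(f"on_fault must be 'skip' or 'abort', got {on_fault!r}")
        self.on_fault = on_fault
        self.report_sink = report_sink
        self.reports: list[tuple[str, str]] = []

    def handle(self, fault: DataFault) -> None:
        """Record the fault (SKIP) or raise :class:`ProcessingAborted` (ABORT)."""
        if self.on_fault == self.ABORT:
            raise ProcessingAborted(fault)
        self.reports.append((fault.seq_id, fault.reason))
        if self.report_sink is not None:
            self.report_sink(f"SKIP {fault.seq_id}: {fault.reason}")


class TypeRegistry:
    """Registry of sequence types; DNA, RNA and PROT are pre-registered."""

    def __init__(self, with_builtins: bool = True):
        self._types: dict[str, SequenceType] = {}
        if with_builtins:
            for st in builtin_seqtypes():
                self._types[st.name] = st

    def register(self, seqtype: SequenceType) -> SequenceType:
        if seqtype.name in self._types:
            raise DefinitionError(f"sequence type {seqtype.name!r} already registered")
        self._types[seqtype.name] = seqtype
        return seqtype

    def unregister(self, name: str) -> None:
        self._types.pop(name, None)

    def get(self, name: str) -> SequenceType:
        try:
            return self._types[name]
        except KeyError:
            raise DefinitionError(
                f"unknown sequence type {name!r}; known: {', '.join(sorted(self._types))}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._types

    def names(self) -> list[str]:
        return sorted(self._types)


_PROT_LETTERS = "ACDEFGHIKLMNPQRSTVWY"  # the 20 standard residues, alphabetical


def builtin_seqtypes() -> list[SequenceType]:
    """The three built-in types: DNA, RNA (with complements) and PROT."""
    return [
        SequenceType("DNA", tuple("ACGT"), {"A": "T", "T": "A", "C": "G", "G": "C"}),
        SequenceType("RNA", tuple("ACGU"), {"A": "U", "U": "A", "C": "G", "G": "C"}),
        SequenceType("PROT", tuple(_PROT_LETTERS), None),
    ]


#: Process-wide default registry (fresh registries can be made for isolation).
SEQTYPES = TypeRegistry()


def define_seqtype(
    name: str,
    alphabet: Iterable[str],
    complement_map: Mapping[str, str] | None = None,
    case_fold: bool = True,
    registry: TypeRegistry | None = None,
) -> SequenceType:
    """Define and register a sequence type (user-defined alphabets allowed).

    Examples include adding an extra letter for a modified residue, e.g. an
    ``M`` for 5-methyl-cytosine alongside the four DNA bases.
    """
    st = SequenceType(name, tuple(alphabet), complement_map, case_fold)
    return (registry or SEQTYPES).register(st)


def get_seqtype(name: str, registry: TypeRegistry | None = None) -> SequenceType:
    return (registry or SEQTYPES).get(name)


def load_seqtype_file(
    source, registry: TypeRegistry | None = None
) -> SequenceType:
    """Load a sequence-type definition from a keyed plain-text file.

    Format: one ``key=value`` entry per line — ``name=`` (required),
    ``alphabet=`` (letters, optionally comma-separated; required),
    ``complement=`` (pairs like ``A:T,C:G``), ``case_fold=yes|no``
    (default yes).  Blank lines and ``#`` comments are ignored.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        from pathlib import Path

        text = Path(source).read_text()
    fields: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise DefinitionError(f"seqtype file line {lineno}: expected key=value")
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    if "name" not in fields or "alphabet" not in fields:
        raise DefinitionError("seqtype file must define 'name=' and 'alphabet='")
    letters = [c for c in fields["alphabet"].replace(",", "") if not c.isspace()]
    complement = None
    if fields.get("complement"):
        complement = {}
        for pair in fields["complement"].split(","):
            a, _, b = pair.strip().partition(":")
            complement[a.strip()] = b.strip()
    case_fold = fields.get("case_fold", "yes").lower() not in ("no", "false", "0")
    return define_seqtype(
        fields["name"], letters, complement, case_fold, registry=registry
    )


def encode_sequence(
    record: SequenceRecord, seqtype: SequenceType, policy: FaultPolicy
) -> IndexArray | None:
    """Encode one record under the fault policy.

    Returns the :class:`IndexArray`, or ``None`` if the record was skipped
    (SKIP policy).  Under ABORT a :class:`ProcessingAborted` propagates.
    """
    try:
        return seqtype.encode(record.id, record.letters)
    except DataFault as fault:
        policy.handle(fault)
        return None
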