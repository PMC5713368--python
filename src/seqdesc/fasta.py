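"""Multi-line FASTA parsing with database header-dialect recognition.

Headers downloaded from UniProt, GenBank, EMBL, DDBJ and RefSeq are
recognized automatically and the accession extracted as the record
identifier; anything else falls back to the whole header line as the
identifier.  Identifiers must be unique within a file.

Dialect rules (first match wins, no backtracking):

1. UniProt          ``sp|ACC|ENTRY`` or ``tr|ACC|ENTRY``
2. NCBI legacy      ``gi|N|db|ACC|`` with db in gb/ref/emb/dbj
3. ENA style        ``ENA|ACC|ACC.V``
4. RefSeq modern    first token like ``NM_000546.6`` (two letters,
                    underscore, digits, optional version)
5. GenBank/DDBJ     first token like ``U49845.1`` (1-2 letters, 5-6
                    digits, optional version); GenBank and DDBJ
                    accessions share a namespace, so both are tagged
                    GENBANK (a documented limitation)
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .alphabet import (
    DataFault,
    FaultPolicy,
    ParseError,
    SequenceRecord,
    SequenceType,
)

__all__ = ["HeaderParse", "recognize_header", "parse_fasta", "write_fasta"]


@dataclass(frozen=True)
class HeaderParse:
    """Result of header recognition: database tag, accession, comment."""

    db: str
    identifier: str
    comment: str


_UNIPROT = re.compile(r"(?:sp|tr)\|([^|\s]+)\|(.*)$")
_NCBI_GI = re.compile(r"gi\|\d+\|(gb|ref|emb|dbj)\|([^|\s]+)\|?\s*(.*)$")
_ENA = re.compile(r"ENA\|([^|\s]+)\|(\S+)\s*(.*)$")
_REFSEQ = re.compile(r"([A-Z]{2}_\d+(?:\.\d+)?)(?:\s+(.*))?$")
_GENBANK = re.compile(r"([A-Z]{1,2}\d{5,6}(?:\.\d+)?)(?:\s+(.*))?$")

_GI_DB = {"gb": "GENBANK", "ref": "REFSEQ", "emb": "EMBL", "dbj": "DDBJ"}


def recognize_header(header_line: str) -> HeaderParse:
    """Extract (db, identifier, comment) from a ``>`` header line.

    Always returns; an unrecognized dialect yields db=UNKNOWN with the
    full header text (minus ``>``) as the identifier and an empty comment.
    """
    text = header_line.lstrip(">").strip()

    m = _UNIPROT.match(text)
    if m:
        return HeaderParse("UNIPROT", m.group(1), m.group(2).strip())
    m = _NCBI_GI.match(text)
    if m:
        return HeaderParse(_GI_DB[m.group(1)], m.group(2), m.group(3).strip())
    m = _ENA.match(text)
    if m:
        return HeaderParse("EMBL", m.group(1), m.group(3).strip())
    m = _REFSEQ.match(text)
    if m:
        return HeaderParse("REFSEQ", m.group(1), (m.group(2) or "").strip())
    m = _GENBANK.match(text)
    if m:
        return HeaderParse("GENBANK", m.group(1), (m.group(2) or "").strip())
    return HeaderParse("UNKNOWN", text, "")


def _as_handle(source: str | Path | TextIO | Iterable[str]) -> TextIO:
    if isinstance(source, Path):
        return source.open()
    if isinstance(source, str):
        if not source or source.lstrip().startswith(">") or "\n" in source:
            return io.StringIO(source)
        return open(source)
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    return io.StringIO("".join(source))


def parse_fasta(
    source: str | Path | TextIO | Iterable[str],
    seqtype: SequenceType | None = None,
    policy: FaultPolicy | None = None,
) -> list[SequenceRecord]:
    """Parse multi-line FASTA into :class:`SequenceRecord` objects.

    ``source`` may be a path, an open text handle, FASTA text itself, or an
    iterable of lines.  LF and CRLF line endings and a missing trailing
    newline are accepted.  Record order follows file order.

    Records with an empty sequence are data faults routed through
    ``policy`` (default SKIP).  Duplicate extracted identifiers from
    distinct header lines fall back to the whole header line as identifier;
    identifiers still duplicated after that raise :class:`ParseError`
    (identifiers must be unique within a file).
    """
    policy = policy or FaultPolicy()
    handle = _as_handle(source)
    entries = [(title, seq) for title, seq in SimpleFastaParser(handle)]
    if not entries:
        raise ParseError("empty FASTA input: no '>' records found")

    parses = [recognize_header(">" + title) for title, _ in entries]
    ids = [hp.identifier for hp in parses]
    # Extracted-ID collisions from distinct header lines fall back to the
    # whole line; identical header lines are unrecoverable duplicates.
    seen: dict[str, int] = {}
    for i, ident in enumerate(ids):
        seen[ident] = seen.get(ident, 0) + 1
    for i, (hp, (title, _)) in enumerate(zip(parses, entries)):
        if seen[hp.identifier] > 1:
            parses[i] = HeaderParse("UNKNOWN", title.strip(), "")
    final_seen: set[str] = set()
    for hp in parses:
        if hp.identifier in final_seen:
            raise ParseError(f"duplicate identifier {hp.identifier!r}")
        final_seen.add(hp.identifier)

    records: list[SequenceRecord] = []
    for hp, (title, seq) in zip(parses, entries):
        letters = re.sub(r"\s+", "", seq)
        if not letters:
            policy.handle(DataFault(hp.identifier, "empty sequence"))
            continue
        records.append(
            SequenceRecord(id=hp.identifier, letters=letters, db=hp.db, comment=hp.comment)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], handle: TextIO) -> None:
    """Serialize records as single-line FASTA (``>id comment`` then sequence)."""
    for rec in records:
        header = f">{rec.id} {rec.comment}".rstrip()
        handle.write(f"{header}\n{rec.letters}\n")
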