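"""Result writers: libSVM (svmlight), TSV and CSV.

All three writers print the same numeric values with the same pinned
formatting — shortest decimal representation at 6 significant digits, no
scientific notation below 1e6 — so results are format-independent and
round-trip to the printed precision.
"""

from __future__ import annotations

import csv
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

from .modes import DescriptorVector

__all__ = ["OutputConfig", "format_value", "write_svm", "write_tabular", "write_output"]

FORMATS = ("svm", "tsv", "csv")


@dataclass
class OutputConfig:
    """Output format, destination and labelling.

    ``labels`` maps sequence id → label for records whose label an
    extension set; everything else gets ``default_label``.  ``sparse``
    drops zero components from libSVM lines (kept by default so every line
    has a fixed column count).
    """

    format: str = "svm"
    destination: str | Path | None = None  # None = standard output
    default_label: object = 0
    labels: Mapping[str, object] | None = None
    precision: int = 6
    sparse: bool = False
    header: bool = False

    def __post_init__(self) -> None:
        if self.format not in FORMATS:
            raise ValueError(f"format must be one of {FORMATS}, got {self.format!r}")

    def label_for(self, seq_id: str):
        if self.labels and seq_id in self.labels:
            return self.labels[seq_id]
        return self.default_label


def format_value(value: float, precision: int = 6) -> str:
    """Shortest positional decimal with ``precision`` significant digits."""
    if value == 0:
        return "0"
    return np.format_float_positional(
        float(value), precision=precision, unique=False, fractional=False, trim="-"
    )


def write_svm(vectors: Sequence[DescriptorVector], config: OutputConfig, handle: TextIO) -> None:
    """One svmlight line per record: ``<label> 1:v1 2:v2 ... D:vD``.

    Indices are 1-based and strictly increasing; zero components are
    emitted unless ``config.sparse``.
    """
    for vec in vectors:
        label = config.label_for(vec.seq_id)
        parts = [str(label)]
        for i, v in enumerate(vec.values, start=1):
            if config.sparse and v == 0:
                continue
            parts.append(f"{i}:{format_value(v, config.precision)}")
        handle.write(" ".join(parts) + "\n")


def write_tabular(
    vectors: Sequence[DescriptorVector], config: OutputConfig, handle: TextIO
) -> None:
    """One row per record: id then values, tab- or comma-separated.

    CSV uses RFC-4180-style quoting (ids containing the delimiter are
    quoted); in TSV an embedded tab in an id is replaced by ``_``.  An
    optional header row names components ``<mode_id>_<index>``.
    """
    delim = "," if config.format == "csv" else "\t"
    if config.format == "csv":
        writer = csv.writer(handle, lineterminator="\n")
        if config.header and vectors:
            writer.writerow(
                ["id"] + [f"{vectors[0].mode_id}_{i + 1}" for i in range(len(vectors[0].values))]
            )
        for vec in vectors:
            writer.writerow(
                [vec.seq_id] + [format_value(v, config.precision) for v in vec.values]
            )
    else:
        if config.header and vectors:
            names = ["id"] + [
                f"{vectors[0].mode_id}_{i + 1}" for i in range(len(vectors[0].values))
            ]
            handle.write(delim.join(names) + "\n")
        for vec in vectors:
            seq_id = vec.seq_id
            if "\t" in seq_id:
                seq_id = seq_id.replace("\t", "_")
                print(f"warning: tab in id replaced: {seq_id}", file=sys.stderr)
            row = [seq_id] + [format_value(v, config.precision) for v in vec.values]
            handle.write(delim.join(row) + "\n")


def write_output(vectors: Sequence[DescriptorVector], config: OutputConfig) -> None:
    """Write to the configured destination (file path or standard output)."""

    def _write(handle: TextIO) -> None:
        if config.format == "svm":
            write_svm(vectors, config, handle)
        else:
            write_tabular(vectors, config, handle)

    if config.destination is None:
        _write(sys.stdout)
    else:
        with open(config.destination, "w") as handle:
            _write(handle)
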