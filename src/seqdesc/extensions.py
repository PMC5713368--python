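"""Runtime-loaded extension files: user modes, properties, sequence types.

An extension is a Python source file executed against a fixed namespace of
23 documented API functions (see :data:`EXTENSION_API_FUNCTIONS`).  Inside
the file, an author can register new sequence types, property tables and
representation modes, declare (or re-bind) command-line options, and —
inside a mode's compute rule — inspect the current sequence and emit its
descriptor vector.

Loading is transactional: if the file raises, nothing it registered
survives.  Mode/type/property identifiers must not collide with built-ins
or earlier extensions.

.. warning::
   Loading an extension **executes arbitrary code** with the privileges of
   the calling process.  Extensions are loaded only from paths given
   explicitly (the ``-d/--tdf`` flag); nothing is auto-loaded from the
   working directory.  No sandboxing is attempted.

Example extension file::

    declare_option("-l", "int", 1, "correlation tiers (lambda)")

    def compute():
        counts = kmer_counts(1)
        emit_vector(counts / counts.sum())

    register_mode("myaac", "PROT", alphabet_size("PROT"), compute)
"""

from __future__ import annotations

import sys
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .alphabet import (
    DataFault,
    DefinitionError,
    IndexArray,
    SequenceError,
    SequenceType,
    TypeRegistry,
)
from . import kernels
from .modes import ModeDefinition, ModeRegistry, default_registry
from .properties import (
    PairCorrelationTable,
    PropertyRegistry,
    PropertyTable,
    build_pair_tables as _build_pair_tables,
    normalize_table,
)

__all__ = [
    "ExtensionError",
    "OptionSpec",
    "ExtensionManifest",
    "ExtensionHost",
    "ExtensionAPI",
    "EXTENSION_API_FUNCTIONS",
    "extension_api",
    "load_extension",
]


class ExtensionError(SequenceError):
    """Extension failed to load or misused the API."""


#: The documented extension API surface: exactly these callables are
#: available (as plain names) inside an extension file.
EXTENSION_API_FUNCTIONS: tuple[str, ...] = (
    "register_seqtype",
    "register_property",
    "register_mode",
    "declare_option",
    "get_option",
    "set_output_format",
    "current_seq_id",
    "current_sequence",
    "current_indices",
    "seq_length",
    "alphabet",
    "alphabet_size",
    "get_property_raw",
    "get_property_normalized",
    "property_value",
    "kmer_counts",
    "theta_parallel",
    "tau_series",
    "build_pair_tables",
    "emit_vector",
    "set_label",
    "skip_sequence",
    "log_message",
)

_OPTION_KINDS = {"int": int, "float": float, "str": str, "flag": bool}


@dataclass(frozen=True)
class OptionSpec:
    """A command-line option declared by an extension."""

    flag: str
    kind: str
    default: object
    help: str

    @property
    def dest(self) -> str:
        return self.flag.lstrip("-").replace("-", "_")


@dataclass
class ExtensionManifest:
    """What one extension file registered."""

    source_path: str
    seqtypes: list[str] = field(default_factory=list)
    properties: list[str] = field(default_factory=list)
    modes: list[str] = field(default_factory=list)
    declared_options: list[OptionSpec] = field(default_factory=list)


class ExtensionHost:
    """Shared registries and option state that extensions plug into."""

    def __init__(
        self,
        modes: ModeRegistry | None = None,
        seqtypes: TypeRegistry | None = None,
        properties: PropertyRegistry | None = None,
    ):
        self.modes = modes if modes is not None else default_registry()
        self.seqtypes = seqtypes if seqtypes is not None else TypeRegistry()
        self.properties = (
            properties if properties is not None else PropertyRegistry(self.seqtypes)
        )
        self.declared_options: list[OptionSpec] = []
        self.options: dict[str, object] = {}
        self.output_format: str | None = None
        self.labels: dict[str, object] = {}
        self.log_lines: list[str] = []

    def option_value(self, name: str):
        name = name.lstrip("-").replace("-", "_")
        if name in self.options:
            return self.options[name]
        for spec in self.declared_options:
            if spec.dest == name:
                return spec.default
        raise ExtensionError(f"unknown option {name!r}")

    def declare(self, spec: OptionSpec) -> None:
        previous = [s for s in self.declared_options if s.dest == spec.dest]
        if previous:
            # Last-loaded declaration wins (option re-binding).
            self.declared_options = [
                s for s in self.declared_options if s.dest != spec.dest
            ]
            print(
                f"warning: option {spec.flag} re-declared, new meaning: {spec.help}",
                file=sys.stderr,
            )
        self.declared_options.append(spec)


class ExtensionAPI:
    """The 23 callables injected into an extension file's namespace.

    Registration functions stage into the host registries immediately and
    are rolled back if the file fails.  The ``current_*`` family is valid
    only inside a mode's compute rule.
    """

    def __init__(self, host: ExtensionHost, source_path: str = "<extension>"):
        self.host = host
        self.source_path = source_path
        self._context: list[tuple[IndexArray, SequenceType]] = []
        self._emitted: np.ndarray | None = None
        # rollback journal for transactional loading
        self._added_seqtypes: list[str] = []
        self._added_properties: list[str] = []
        self._added_modes: list[str] = []
        self._added_options: list[OptionSpec] = []

    # -- context plumbing ---------------------------------------------------

    @contextmanager
    def _sequence(self, seq: IndexArray, seqtype: SequenceType):
        self._context.append((seq, seqtype))
        try:
            yield
        finally:
            self._context.pop()

    def _current(self) -> tuple[IndexArray, SequenceType]:
        if not self._context:
            raise ExtensionError(
                "per-sequence API functions may only be called inside a "
                "mode's compute rule"
            )
        return self._context[-1]

    def _rollback(self) -> None:
        for name in self._added_modes:
            self.host.modes.unregister(name)
        for name in self._added_properties:
            self.host.properties.unregister(name)
        for name in self._added_seqtypes:
            self.host.seqtypes.unregister(name)
        for spec in self._added_options:
            self.host.declared_options = [
                s for s in self.host.declared_options if s is not spec
            ]

    def namespace(self) -> dict:
        ns = {name: getattr(self, name) for name in EXTENSION_API_FUNCTIONS}
        ns["__name__"] = f"seqdesc_extension:{self.source_path}"
        return ns

    # -- registration -------------------------------------------------------

    def register_seqtype(
        self,
        name: str,
        alphabet: Iterable[str],
        complement: Mapping[str, str] | None = None,
        case_fold: bool = True,
    ) -> None:
        """Register a user-defined sequence type (ordered alphabet)."""
        st = SequenceType(name, tuple(alphabet), complement, case_fold)
        self.host.seqtypes.register(st)
        self._added_seqtypes.append(name)

    def register_property(
        self, name: str, seqtype: str, tuple_size: int, values: Mapping[str, float]
    ) -> None:
        """Register a physicochemical property over all |A|^n tuples."""
        st = self.host.seqtypes.get(seqtype)
        table = PropertyTable(
            name=name, seqtype=st.name, tuple_size=int(tuple_size),
            raw={str(k): float(v) for k, v in values.items()},
        )
        expected = set(table.tuples(st))
        if set(table.raw) != expected:
            missing = sorted(expected - set(table.raw))[:5]
            raise ExtensionError(
                f"property {name!r} must cover all tuples; missing {' '.join(missing)}"
            )
        self.host.properties.register(table)
        self._added_properties.append(name)

    def register_mode(
        self,
        mode_id: str,
        seqtype: str,
        dimension: int | Callable[[], int],
        compute: Callable[[], object],
    ) -> None:
        """Register a representation mode.

        ``dimension`` is an integer or a zero-argument callable evaluated
        at configuration time (so it can read declared options).
        ``compute`` is called once per sequence with no arguments; it uses
        the per-sequence API and finishes with :meth:`emit_vector` (or
        returns the vector).  A vector of the wrong length is a data fault
        at first use.
        """
        api = self

        def factory(st: SequenceType, params: dict, props: PropertyRegistry):
            this_id = params.pop("_mode_id", mode_id)
            unknown = {k: v for k, v in params.items() if v is not None}
            if unknown:
                raise DefinitionError(
                    f"extension mode {this_id!r} takes options via declare_option, "
                    f"not parameters {sorted(unknown)}"
                )
            dim = int(dimension()) if callable(dimension) else int(dimension)

            def compute_rule(seq: IndexArray) -> np.ndarray:
                with api._sequence(seq, st):
                    api._emitted = None
                    result = compute()
                    vec = api._emitted
                    if vec is None and result is not None:
                        vec = np.asarray(result, dtype=float)
                    if vec is None:
                        raise DataFault(seq.seq_id, f"mode {this_id!r} emitted no vector")
                    return vec

            return dim, compute_rule

        definition = ModeDefinition(
            mode_id=mode_id,
            seqtype=seqtype,
            description=f"extension mode from {self.source_path}",
            param_names=(),
            factory=factory,
            builtin=False,
        )
        self.host.modes.register(definition)
        self._added_modes.append(mode_id)

    def declare_option(self, flag: str, kind: str, default, help: str = "") -> None:
        """Declare (or re-bind) a command-line option; readable via get_option."""
        if kind not in _OPTION_KINDS:
            raise ExtensionError(
                f"option kind must be one of {sorted(_OPTION_KINDS)}, got {kind!r}"
            )
        spec = OptionSpec(flag=str(flag), kind=kind, default=default, help=help)
        self.host.declare(spec)
        self._added_options.append(spec)

    def get_option(self, name: str):
        """Current value of a declared option (default until the CLI parses)."""
        return self.host.option_value(name)

    def set_output_format(self, fmt: str) -> None:
        """Set the preferred output format (svm, tsv or csv)."""
        fmt = fmt.lower()
        if fmt not in ("svm", "tsv", "csv"):
            raise ExtensionError(f"unknown output format {fmt!r}")
        self.host.output_format = fmt

    # -- per-sequence inspection -------------------------------------------

    def current_seq_id(self) -> str:
        seq, _ = self._current()
        return seq.seq_id

    def current_sequence(self) -> str:
        seq, st = self._current()
        return st.decode(seq.indices)

    def current_indices(self) -> np.ndarray:
        seq, _ = self._current()
        return seq.indices

    def seq_length(self) -> int:
        seq, _ = self._current()
        return seq.length

    def alphabet(self, seqtype: str | None = None) -> tuple[str, ...]:
        return self._seqtype(seqtype).alphabet

    def alphabet_size(self, seqtype: str | None = None) -> int:
        return self._seqtype(seqtype).size

    def _seqtype(self, name: str | None) -> SequenceType:
        if name is not None:
            return self.host.seqtypes.get(name)
        _, st = self._current()
        return st

    # -- property access ----------------------------------------------------

    def get_property_raw(self, name: str) -> dict[str, float]:
        return dict(self.host.properties.get(name).raw)

    def get_property_normalized(self, name: str) -> dict[str, float]:
        table = self.host.properties.get(name)
        if table.normalized is None:
            table = normalize_table(table)
        return dict(table.normalized)

    def property_value(self, name: str, tup: str, normalized: bool = True) -> float:
        table = self.host.properties.get(name)
        source = table.normalized if normalized else table.raw
        if source is None:
            source = normalize_table(table).normalized
        try:
            return source[tup]
        except KeyError:
            raise ExtensionError(f"tuple {tup!r} not in property {name!r}") from None

    def build_pair_tables(
        self, property_names: Sequence[str], combine: str = "average"
    ) -> PairCorrelationTable:
        """Pre-compute Θ/Π tables for a named property set (cache and reuse)."""
        tables = self.host.properties.get_set(property_names)
        st = self.host.seqtypes.get(tables[0].seqtype)
        return _build_pair_tables(tables, st, combine=combine)

    # -- per-sequence computation -------------------------------------------

    def kmer_counts(self, k: int) -> np.ndarray:
        seq, st = self._current()
        return kernels.kmer_counts(seq, k, st.size)

    def theta_parallel(self, lam: int, pair: PairCorrelationTable) -> np.ndarray:
        seq, st = self._current()
        return kernels.theta_parallel(seq, lam, pair, st.size)

    def tau_series(self, lam: int, pair: PairCorrelationTable) -> np.ndarray:
        seq, st = self._current()
        return kernels.tau_series(seq, lam, pair, st.size)

    def emit_vector(self, values) -> None:
        self._current()
        self._emitted = np.asarray(values, dtype=float).ravel()

    def set_label(self, value) -> None:
        seq, _ = self._current()
        self.host.labels[seq.seq_id] = value

    def skip_sequence(self, reason: str = "skipped by extension") -> None:
        seq, _ = self._current()
        raise DataFault(seq.seq_id, reason)

    def log_message(self, message: str) -> None:
        self.host.log_lines.append(str(message))
        print(f"[extension] {message}", file=sys.stderr)


def extension_api(host: ExtensionHost | None = None) -> dict[str, Callable]:
    """The documented API surface as a name → callable mapping (23 entries)."""
    api = ExtensionAPI(host if host is not None else ExtensionHost())
    return {name: getattr(api, name) for name in EXTENSION_API_FUNCTIONS}


def load_extension(path: str | Path, host: ExtensionHost) -> ExtensionManifest:
    """Execute an extension file against the API; transactional.

    On any error (syntax, runtime, identifier collision) nothing the file
    registered survives, and :class:`ExtensionError` reports file and line.
    """
    path = Path(path)
    try:
        source = path.read_text()
    except OSError as exc:
        raise ExtensionError(f"{path}: cannot read extension file ({exc})") from exc
    api = ExtensionAPI(host, source_path=str(path))
    try:
        code = compile(source, str(path), "exec")
        exec(code, api.namespace())
    except ExtensionError:
        api._rollback()
        raise
    except SyntaxError as exc:
        api._rollback()
        raise ExtensionError(
            f"{path}: syntax error at line {exc.lineno}: {exc.msg}"
        ) from exc
    except SequenceError as exc:
        api._rollback()
        raise ExtensionError(f"{path}: {exc}") from exc
    except Exception as exc:
        api._rollback()
        line = getattr(exc.__traceback__.tb_next, "tb_lineno", "?") if exc.__traceback__ else "?"
        raise ExtensionError(f"{path}: error at line {line}: {exc}") from exc
    return ExtensionManifest(
        source_path=str(path),
        seqtypes=list(api._added_seqtypes),
        properties=list(api._added_properties),
        modes=list(api._added_modes),
        declared_options=list(api._added_options),
    )
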