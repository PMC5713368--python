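"""The computing engine: representation-mode registry and execution.

A *mode* is a named, parameterized procedure mapping a sequence to a
fixed-length numeric vector.  :class:`ModeRegistry` holds the 35 built-in
modes (12 DNA, 8 RNA, 15 protein) plus any extension-registered ones;
:func:`configure_mode` resolves parameters and pre-computes the pair
tables once per configuration (never per sequence); :func:`run_engine`
streams encoded sequences through the configured modes under a fault
policy.

Built-in mode identifiers
-------------------------
DNA:  kmer-dna, revkmer-dna, onehot-dna, dac, dcc, dacc, tac, tcc, tacc,
      psednc, pseknc1, pseknc2
RNA:  kmer-rna, onehot-rna, dac-rna, dcc-rna, dacc-rna, psednc-rna,
      sc-psednc-rna, pseknc-rna
PROT: aac, dpc, tpc, onehot-prot, pseaac1, pseaac2, pc-pseaac-g,
      sc-pseaac-g, ac-prot, cc-prot, acc-prot, dr, moran, geary, nmbroto
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .alphabet import (
    DataFault,
    DefinitionError,
    FaultPolicy,
    IndexArray,
    SequenceRecord,
    SequenceType,
    TypeRegistry,
    SEQTYPES,
    encode_sequence,
)
from . import kernels
from .properties import (
    PairCorrelationTable,
    PropertyRegistry,
    build_pair_tables,
)

__all__ = [
    "ModeDefinition",
    "ConfiguredMode",
    "DescriptorVector",
    "ModeRegistry",
    "default_registry",
    "list_modes",
    "configure_mode",
    "run_engine",
]

#: Parameter defaults shared across modes.
DEFAULTS = {"lam": 1, "omega": 0.05, "d_max": 1}


@dataclass
class DescriptorVector:
    """Fixed-length numeric representation of one sequence."""

    seq_id: str
    mode_id: str
    values: np.ndarray
    label: object = None


@dataclass
class ModeDefinition:
    """A registered representation mode.

    ``factory(seqtype, params, properties)`` validates parameters and
    returns ``(dimension, compute)`` where ``compute`` maps an
    :class:`IndexArray` to a vector of exactly ``dimension`` entries.
    ``param_names`` lists the parameters the mode accepts; anything else
    passed at configuration time is a configuration error.
    """

    mode_id: str
    seqtype: str
    description: str
    param_names: tuple[str, ...]
    factory: Callable[
        [SequenceType, dict, PropertyRegistry], tuple[int, Callable[[IndexArray], np.ndarray]]
    ]
    builtin: bool = True

    def summary(self) -> dict:
        return {
            "mode_id": self.mode_id,
            "seqtype": self.seqtype,
            "params": list(self.param_names),
            "description": self.description,
        }


@dataclass
class ConfiguredMode:
    """A mode bound to resolved parameters and pre-built tables."""

    mode_id: str
    seqtype: SequenceType
    dimension: int
    compute: Callable[[IndexArray], np.ndarray]


class ModeRegistry:
    """Registry of representation modes; identifiers are unique."""

    def __init__(self, definitions: Iterable[ModeDefinition] = ()):
        self._modes: dict[str, ModeDefinition] = {}
        for d in definitions:
            self.register(d)

    def register(self, definition: ModeDefinition) -> ModeDefinition:
        if definition.mode_id in self._modes:
            raise DefinitionError(f"mode {definition.mode_id!r} already registered")
        self._modes[definition.mode_id] = definition
        return definition

    def unregister(self, mode_id: str) -> None:
        self._modes.pop(mode_id, None)

    def get(self, mode_id: str) -> ModeDefinition:
        try:
            return self._modes[mode_id]
        except KeyError:
            raise DefinitionError(
                f"unknown mode {mode_id!r}; valid modes: "
                + ", ".join(sorted(self._modes))
            ) from None

    def __contains__(self, mode_id: str) -> bool:
        return mode_id in self._modes

    def __len__(self) -> int:
        return len(self._modes)

    def list_modes(self, seqtype: str | None = None) -> list[ModeDefinition]:
        """Catalogue, stable-sorted by (seqtype, mode_id)."""
        defs = [
            d
            for d in self._modes.values()
            if seqtype is None or d.seqtype == seqtype
        ]
        return sorted(defs, key=lambda d: (d.seqtype, d.mode_id))


# ---------------------------------------------------------------------------
# Parameter handling
# ---------------------------------------------------------------------------


def _resolve(params: Mapping, allowed: tuple[str, ...], mode_id: str, **fixed) -> dict:
    params = {k: v for k, v in dict(params).items() if v is not None}
    unknown = set(params) - set(allowed)
    if unknown:
        raise DefinitionError(
            f"mode {mode_id!r} does not accept parameter(s): {', '.join(sorted(unknown))}"
        )
    out = dict(fixed)
    out.update(params)
    return out


def _int_param(cfg: dict, name: str, mode_id: str, minimum: int = 0) -> int:
    try:
        value = int(cfg[name])
    except (TypeError, ValueError):
        raise DefinitionError(f"mode {mode_id!r}: parameter {name} must be an integer") from None
    if value < minimum:
        raise DefinitionError(f"mode {mode_id!r}: parameter {name} must be >= {minimum}")
    return value


def _float_param(cfg: dict, name: str, mode_id: str) -> float:
    try:
        return float(cfg[name])
    except (TypeError, ValueError):
        raise DefinitionError(f"mode {mode_id!r}: parameter {name} must be a number") from None


def _resolve_props(
    cfg: dict, props: PropertyRegistry, seqtype: SequenceType, tuple_size: int, mode_id: str
):
    names = cfg.get("props")
    if names is None:
        names = props.default_set(seqtype.name, tuple_size)
    elif isinstance(names, str):
        names = tuple(p.strip() for p in names.split(",") if p.strip())
    tables = props.get_set(names)
    for t in tables:
        if t.seqtype != seqtype.name:
            raise DefinitionError(
                f"mode {mode_id!r}: property {t.name!r} is for seqtype {t.seqtype!r}, "
                f"not {seqtype.name!r}"
            )
        if t.tuple_size != tuple_size:
            raise DefinitionError(
                f"mode {mode_id!r}: property {t.name!r} has tuple size {t.tuple_size}, "
                f"expected {tuple_size}"
            )
    return tables


# ---------------------------------------------------------------------------
# Built-in mode factories
# ---------------------------------------------------------------------------


def _kmer_factory(default_k: int, collapse: bool = False):
    def factory(seqtype: SequenceType, params: dict, props: PropertyRegistry):
        mode_id = params.pop("_mode_id")
        cfg = _resolve(params, ("k",), mode_id, k=default_k)
        k = _int_param(cfg, "k", mode_id, minimum=1)
        if collapse:
            _, dim = kernels.canonical_kmer_classes(seqtype, k)
        else:
            dim = seqtype.size**k
        def compute(seq: IndexArray) -> np.ndarray:
            return kernels.kmer_composition(seq, k, seqtype, collapse_revcomp=collapse)
        return dim, compute

    return factory


def _onehot_factory(seqtype_obj_unused=None):
    def factory(seqtype: SequenceType, params: dict, props: PropertyRegistry):
        mode_id = params.pop("_mode_id")
        cfg = _resolve(params, ("target_length",), mode_id)
        if "target_length" not in cfg:
            raise DefinitionError(
                f"mode {mode_id!r}: target_length is required (no default)"
            )
        target = _int_param(cfg, "target_length", mode_id, minimum=1)
        dim = target * seqtype.size

        def compute(seq: IndexArray) -> np.ndarray:
            return kernels.one_hot(seq, target, seqtype.size)

        return dim, compute

    return factory


def _pse_factory(pse_type: int, corr_tuple: int, default_k: int, fixed_k: bool = False,
                 fixed_props: tuple[str, ...] | None = None):
    """Pseudo-composition factory.

    ``corr_tuple`` is the correlation tuple size n (1 for amino-acid
    properties, 2 for dinucleotides); the composition tuple size k is an
    independent parameter unless ``fixed_k``.
    """

    def factory(seqtype: SequenceType, params: dict, props: PropertyRegistry):
        mode_id = params.pop("_mode_id")
        allowed = ("lam", "omega") + (() if fixed_k else ("k",)) + (
            () if fixed_props else ("props",)
        )
        cfg = _resolve(params, allowed, mode_id, lam=DEFAULTS["lam"],
                       omega=DEFAULTS["omega"], k=default_k)
        k = default_k if fixed_k else _int_param(cfg, "k", mode_id, minimum=1)
        lam = _int_param(cfg, "lam", mode_id, minimum=0)
        omega = _float_param(cfg, "omega", mode_id)
        if omega <= 0:
            raise DefinitionError(f"mode {mode_id!r}: omega must be > 0")
        if fixed_props:
            cfg["props"] = fixed_props
        tables = _resolve_props(cfg, props, seqtype, corr_tuple, mode_id)
        pair = build_pair_tables(tables, seqtype)  # built once per configuration
        gamma = pair.n_properties
        dim = seqtype.size**k + (lam if pse_type == 1 else lam * gamma)
        kernel = kernels.pse_type1 if pse_type == 1 else kernels.pse_type2

        def compute(seq: IndexArray) -> np.ndarray:
            return kernel(seq, k, lam, omega, pair, seqtype)

        return dim, compute

    return factory


def _autocorr_factory(method: str, corr_tuple: int, fixed_props=None):
    def factory(seqtype: SequenceType, params: dict, props: PropertyRegistry):
        mode_id = params.pop("_mode_id")
        allowed = ("d_max",) + (() if fixed_props else ("props",))
        cfg = _resolve(params, allowed, mode_id, d_max=DEFAULTS["d_max"])
        d_max = _int_param(cfg, "d_max", mode_id, minimum=1)
        if fixed_props:
            cfg["props"] = fixed_props
        tables = _resolve_props(cfg, props, seqtype, corr_tuple, mode_id)
        tables = [t for t in tables]
        gamma = len(tables)
        if method in ("CC", "ACC") and gamma < 2:
            raise DefinitionError(
                f"mode {mode_id!r}: cross-covariance needs at least two properties"
            )
        per_lag = {"AC": gamma, "MORAN": gamma, "GEARY": gamma, "NMBROTO": gamma,
                   "CC": gamma * (gamma - 1), "ACC": gamma * gamma}[method]
        dim = d_max * per_lag

        def compute(seq: IndexArray) -> np.ndarray:
            return kernels.autocorrelation(seq, method, d_max, tables, seqtype)

        return dim, compute

    return factory


def _distance_pair_factory():
    def factory(seqtype: SequenceType, params: dict, props: PropertyRegistry):
        mode_id = params.pop("_mode_id")
        cfg = _resolve(params, ("d_max",), mode_id, d_max=DEFAULTS["d_max"])
        d_max = _int_param(cfg, "d_max", mode_id, minimum=1)
        dim = d_max * seqtype.size**2

        def compute(seq: IndexArray) -> np.ndarray:
            return kernels.distance_pair(seq, d_max, seqtype.size)

        return dim, compute

    return factory


_PROT_TRIO = ("hydrophobicity", "hydrophilicity", "side-chain-mass")
_PROT_DUO = ("hydrophobicity", "hydrophilicity")


def _builtin_definitions() -> list[ModeDefinition]:
    D = ModeDefinition
    defs = [
        # --- DNA (12) ---
        D("kmer-dna", "DNA", "k-tuple nucleotide composition", ("k",), _kmer_factory(2)),
        D("revkmer-dna", "DNA", "reverse-complement-collapsed k-tuple composition",
          ("k",), _kmer_factory(2, collapse=True)),
        D("onehot-dna", "DNA", "one-hot encoding padded to a target length",
          ("target_length",), _onehot_factory()),
        D("dac", "DNA", "dinucleotide-property autocovariance", ("d_max", "props"),
          _autocorr_factory("AC", 2)),
        D("dcc", "DNA", "dinucleotide-property cross-covariance", ("d_max", "props"),
          _autocorr_factory("CC", 2)),
        D("dacc", "DNA", "dinucleotide-property auto+cross covariance", ("d_max", "props"),
          _autocorr_factory("ACC", 2)),
        D("tac", "DNA", "trinucleotide-property autocovariance", ("d_max", "props"),
          _autocorr_factory("AC", 3)),
        D("tcc", "DNA", "trinucleotide-property cross-covariance", ("d_max", "props"),
          _autocorr_factory("CC", 3)),
        D("tacc", "DNA", "trinucleotide-property auto+cross covariance", ("d_max", "props"),
          _autocorr_factory("ACC", 3)),
        D("psednc", "DNA", "pseudo dinucleotide composition (type 1, k=2)",
          ("lam", "omega", "props"), _pse_factory(1, 2, 2, fixed_k=True)),
        D("pseknc1", "DNA", "pseudo k-tuple composition, parallel correlation",
          ("k", "lam", "omega", "props"), _pse_factory(1, 2, 3)),
        D("pseknc2", "DNA", "pseudo k-tuple composition, series correlation",
          ("k", "lam", "omega", "props"), _pse_factory(2, 2, 3)),
        # --- RNA (8) ---
        D("kmer-rna", "RNA", "k-tuple nucleotide composition", ("k",), _kmer_factory(2)),
        D("onehot-rna", "RNA", "one-hot encoding padded to a target length",
          ("target_length",), _onehot_factory()),
        D("dac-rna", "RNA", "dinucleotide-property autocovariance", ("d_max", "props"),
          _autocorr_factory("AC", 2)),
        D("dcc-rna", "RNA", "dinucleotide-property cross-covariance", ("d_max", "props"),
          _autocorr_factory("CC", 2)),
        D("dacc-rna", "RNA", "dinucleotide-property auto+cross covariance",
          ("d_max", "props"), _autocorr_factory("ACC", 2)),
        D("psednc-rna", "RNA", "pseudo dinucleotide composition (type 1, k=2)",
          ("lam", "omega", "props"), _pse_factory(1, 2, 2, fixed_k=True)),
        D("sc-psednc-rna", "RNA", "series-correlation pseudo dinucleotide composition (k=2)",
          ("lam", "omega", "props"), _pse_factory(2, 2, 2, fixed_k=True)),
        D("pseknc-rna", "RNA", "pseudo k-tuple composition, parallel correlation",
          ("k", "lam", "omega", "props"), _pse_factory(1, 2, 3)),
        # --- PROT (15) ---
        D("aac", "PROT", "amino-acid composition", (), _kmer_factory(1)),
        D("dpc", "PROT", "dipeptide composition", (), _kmer_factory(2)),
        D("tpc", "PROT", "tripeptide composition", (), _kmer_factory(3)),
        D("onehot-prot", "PROT", "one-hot encoding padded to a target length",
          ("target_length",), _onehot_factory()),
        D("pseaac1", "PROT", "classic type-1 pseudo-amino-acid composition "
          "(hydrophobicity/hydrophilicity/side-chain-mass)",
          ("lam", "omega"), _pse_factory(1, 1, 1, fixed_k=True, fixed_props=_PROT_TRIO)),
        D("pseaac2", "PROT", "classic type-2 (amphiphilic) pseudo-amino-acid composition "
          "(hydrophobicity/hydrophilicity)",
          ("lam", "omega"), _pse_factory(2, 1, 1, fixed_k=True, fixed_props=_PROT_DUO)),
        D("pc-pseaac-g", "PROT", "general parallel-correlation pseudo composition, "
          "user property set", ("lam", "omega", "props"),
          _pse_factory(1, 1, 1, fixed_k=True)),
        D("sc-pseaac-g", "PROT", "general series-correlation pseudo composition, "
          "user property set", ("lam", "omega", "props"),
          _pse_factory(2, 1, 1, fixed_k=True)),
        D("ac-prot", "PROT", "amino-acid property autocovariance", ("d_max", "props"),
          _autocorr_factory("AC", 1)),
        D("cc-prot", "PROT", "amino-acid property cross-covariance", ("d_max", "props"),
          _autocorr_factory("CC", 1)),
        D("acc-prot", "PROT", "amino-acid property auto+cross covariance",
          ("d_max", "props"), _autocorr_factory("ACC", 1)),
        D("dr", "PROT", "distance-pair residue frequencies", ("d_max",),
          _distance_pair_factory()),
        D("moran", "PROT", "Moran autocorrelation of amino-acid properties",
          ("d_max", "props"), _autocorr_factory("MORAN", 1)),
        D("geary", "PROT", "Geary autocorrelation of amino-acid properties",
          ("d_max", "props"), _autocorr_factory("GEARY", 1)),
        D("nmbroto", "PROT", "normalized Moreau-Broto autocorrelation",
          ("d_max", "props"), _autocorr_factory("NMBROTO", 1)),
    ]
    # aac/dpc/tpc have a fixed k baked into the factory default and accept
    # no parameters; enforce by narrowing the factory's allowed set.
    fixed_k = {"aac": 1, "dpc": 2, "tpc": 3}
    for d in defs:
        if d.mode_id in fixed_k:
            d.factory = _fixed_kmer_factory(fixed_k[d.mode_id])
    return defs


def _fixed_kmer_factory(k: int):
    def factory(seqtype: SequenceType, params: dict, props: PropertyRegistry):
        mode_id = params.pop("_mode_id")
        _resolve(params, (), mode_id)
        dim = seqtype.size**k

        def compute(seq: IndexArray) -> np.ndarray:
            return kernels.kmer_composition(seq, k, seqtype)

        return dim, compute

    return factory


def default_registry() -> ModeRegistry:
    """A fresh registry holding exactly the 35 built-in modes."""
    return ModeRegistry(_builtin_definitions())


def list_modes(
    registry: ModeRegistry | None = None, seqtype: str | None = None
) -> list[dict]:
    """Catalogue summaries, sorted by (seqtype, mode_id)."""
    registry = registry if registry is not None else default_registry()
    return [d.summary() for d in registry.list_modes(seqtype)]


def configure_mode(
    mode_id: str,
    seqtype: SequenceType | str,
    registry: ModeRegistry | None = None,
    properties: PropertyRegistry | None = None,
    seqtypes: TypeRegistry | None = None,
    **params,
) -> ConfiguredMode:
    """Resolve a mode's parameters and pre-compute its tables.

    Parameter validation is dataset-independent; length-dependent problems
    surface later as per-sequence data faults.
    """
    registry = registry if registry is not None else default_registry()
    properties = properties if properties is not None else PropertyRegistry(seqtypes)
    if isinstance(seqtype, str):
        seqtype = (seqtypes or SEQTYPES).get(seqtype)
    definition = registry.get(mode_id)
    if definition.seqtype != seqtype.name:
        raise DefinitionError(
            f"mode {mode_id!r} is defined for seqtype {definition.seqtype!r}, "
            f"not {seqtype.name!r}"
        )
    call_params = dict(params)
    call_params["_mode_id"] = mode_id
    dimension, compute = definition.factory(seqtype, call_params, properties)
    return ConfiguredMode(mode_id=mode_id, seqtype=seqtype, dimension=dimension,
                          compute=compute)


def run_engine(
    records: Sequence[SequenceRecord],
    seqtype: SequenceType,
    modes: Sequence[ConfiguredMode],
    policy: FaultPolicy | None = None,
) -> list[DescriptorVector]:
    """Encode records and run every configured mode over each.

    Per record the mode vectors are concatenated in request order.  Data
    faults (bad letter, insufficient length, degenerate denominator) are
    routed through the policy: under SKIP the record is dropped and
    reported once; under ABORT processing stops.  Output order equals
    input order minus skipped records.
    """
    if not modes:
        raise DefinitionError("at least one mode must be configured")
    for m in modes:
        if m.seqtype.name != seqtype.name:
            raise DefinitionError(
                f"mode {m.mode_id!r} configured for {m.seqtype.name!r}, "
                f"engine running {seqtype.name!r}"
            )
    policy = policy or FaultPolicy()
    mode_tag = ",".join(m.mode_id for m in modes)
    out: list[DescriptorVector] = []
    for rec in records:
        seq = encode_sequence(rec, seqtype, policy)
        if seq is None:
            continue
        try:
            parts = []
            for m in modes:
                vec = np.asarray(m.compute(seq), dtype=float)
                if vec.shape != (m.dimension,):
                    raise DataFault(
                        rec.id,
                        f"mode {m.mode_id!r} emitted {vec.shape[0] if vec.ndim == 1 else vec.shape} "
                        f"values, expected {m.dimension}",
                    )
                parts.append(vec)
        except DataFault as fault:
            policy.handle(fault)
            continue
        out.append(DescriptorVector(rec.id, mode_tag, np.concatenate(parts)))
    return out
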