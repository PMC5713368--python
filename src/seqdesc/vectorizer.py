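"""scikit-learn transformer over the descriptor engine.

:class:`SequenceVectorizer` turns variable-length sequences into a
fixed-width numeric matrix, so it composes directly with sklearn
pipelines, feature unions and model selection.  It is stateless in the
statistical sense — ``fit`` only resolves parameters and pre-computes the
alphabet-level tables — but follows the estimator contract (``get_params``
/ ``set_params``, fitted attributes with trailing underscores, validation
in ``fit``).

``transform`` is strict: a data fault (non-standard letter, sequence too
short for the requested lags) raises ``ValueError`` so the output row
count always matches the input.  Skip-and-report batch semantics live in
:func:`seqdesc.modes.run_engine` and the command-line interface.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .alphabet import (
    DataFault,
    SequenceRecord,
    SequenceType,
    TypeRegistry,
    SEQTYPES,
)
from .modes import ModeRegistry, configure_mode, default_registry
from .properties import PropertyRegistry

__all__ = ["SequenceVectorizer"]


class SequenceVectorizer(TransformerMixin, BaseEstimator):
    """Map sequences to fixed-length descriptor vectors.

    Parameters
    ----------
    mode:
        Mode identifier from the built-in catalogue (see
        :func:`seqdesc.modes.list_modes`) or an extension-registered mode.
    seqtype:
        Sequence type name ("PROT", "DNA", "RNA" or user-defined).
    lam, omega:
        λ correlation-tier count and ω weight for pseudo-composition
        modes.  ``None`` leaves the mode's default (λ=1, ω=0.05).
    k:
        Composition tuple size for general-k modes.
    d_max:
        Maximum lag/distance for autocorrelation and distance-pair modes.
    target_length:
        Mandatory for one-hot modes; the padded sequence length.
    props:
        Property-table names (sequence of names or comma-joined string)
        for correlation modes; ``None`` uses the mode's default set.
    registry, properties, seqtypes:
        Optional registries, for extension-loaded modes or isolated tests.

    Attributes
    ----------
    dimension_ : int
        Output vector length (constant for fixed parameters).
    n_features_out_ : int
        Alias of ``dimension_``.
    seqtype_ : SequenceType
        Resolved sequence type.

    Examples
    --------
    >>> vec = SequenceVectorizer(mode="aac")
    >>> vec.fit_transform(["ACDEFGHIKL", "MNPQRSTVWY"]).shape
    (2, 20)
    """

    def __init__(
        self,
        mode: str = "aac",
        seqtype: str = "PROT",
        lam: int | None = None,
        omega: float | None = None,
        k: int | None = None,
        d_max: int | None = None,
        target_length: int | None = None,
        props: Sequence[str] | str | None = None,
        registry: ModeRegistry | None = None,
        properties: PropertyRegistry | None = None,
        seqtypes: TypeRegistry | None = None,
    ):
        self.mode = mode
        self.seqtype = seqtype
        self.lam = lam
        self.omega = omega
        self.k = k
        self.d_max = d_max
        self.target_length = target_length
        self.props = props
        self.registry = registry
        self.properties = properties
        self.seqtypes = seqtypes

    def fit(self, X: Iterable | None = None, y=None) -> "SequenceVectorizer":
        """Validate parameters and pre-compute mode tables (data-independent)."""
        seqtypes = self.seqtypes or SEQTYPES
        self.seqtype_ = (
            self.seqtype if isinstance(self.seqtype, SequenceType)
            else seqtypes.get(self.seqtype)
        )
        registry = self.registry if self.registry is not None else default_registry()
        params = {
            name: getattr(self, name)
            for name in ("lam", "omega", "k", "d_max", "target_length", "props")
            if getattr(self, name) is not None
        }
        self._configured = configure_mode(
            self.mode,
            self.seqtype_,
            registry=registry,
            properties=self.properties,
            seqtypes=seqtypes,
            **params,
        )
        self.dimension_ = self._configured.dimension
        self.n_features_out_ = self.dimension_
        return self

    def transform(self, X: Iterable) -> np.ndarray:
        """Vectorize sequences (strings or :class:`SequenceRecord`)."""
        if not hasattr(self, "_configured"):
            raise ValueError("SequenceVectorizer is not fitted; call fit first")
        rows = []
        for i, item in enumerate(X):
            if isinstance(item, SequenceRecord):
                seq_id, letters = item.id, item.letters
            else:
                seq_id, letters = f"seq{i}", str(item)
            try:
                encoded = self.seqtype_.encode(seq_id, letters)
                rows.append(self._configured.compute(encoded))
            except DataFault as fault:
                raise ValueError(f"data fault in input sequence: {fault}") from fault
        if not rows:
            return np.empty((0, self.dimension_))
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        if not hasattr(self, "dimension_"):
            raise ValueError("SequenceVectorizer is not fitted; call fit first")
        return np.array(
            [f"{self.mode}_{i + 1}" for i in range(self.dimension_)], dtype=object
        )


def vectorize(sequences: Iterable, mode: str = "aac", seqtype: str = "PROT", **params
              ) -> np.ndarray:
    """Functional one-shot wrapper around :class:`SequenceVectorizer`."""
    return SequenceVectorizer(mode=mode, seqtype=seqtype, **params).fit(None).transform(sequences)
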