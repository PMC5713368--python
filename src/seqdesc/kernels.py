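"""Numeric kernels: IndexArray → fixed-length descriptor vector.

All kernels take pre-encoded index arrays and, where correlations are
involved, a :class:`~seqdesc.properties.PairCorrelationTable`, so the
per-sequence work is pure table lookup and vectorized arithmetic.

Notation (1-based, as in the descriptor literature): a sequence of length
L has residues R_1..R_L; with correlation tuple size n there are
N = L−n+1 overlapping tuples D_i = (R_i..R_{i+n−1}).

Composition:   f_u = count(u) / (L−k+1), u over the |A|^k k-tuples.
Parallel tier: θ_j = (1/(N−j)) Σ_i Θ(D_i, D_{i+j}),      j = 1..λ.
Series tier:   τ_{(j−1)Γ+v} = (1/(N−j)) Σ_i Π_v(D_i, D_{i+j})
               (lag-major, property-minor; for Γ=2 this reproduces the
               classic τ_{2j−1}, τ_{2j} interleaving).
Type-1 pseudo-composition: Z = 1 + ω Σ θ;  x_u = f_u/Z,
               x_{|A|^k+j} = ω θ_j / Z.
Type-2 pseudo-composition: same with τ replacing θ (pseudo components may
               be negative; Z may degenerate to 0, a data fault).

The autocorrelation family (AC/CC/ACC, Moran, Geary, Moreau-Broto) and the
distance-pair descriptor are documented at their functions.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Sequence

import numpy as np

from .alphabet import DataFault, IndexArray, SequenceType
from .properties import PairCorrelationTable, PropertyTable, tuple_indices

__all__ = [
    "kmer_counts",
    "kmer_composition",
    "canonical_kmer_classes",
    "theta_parallel",
    "tau_series",
    "pse_type1",
    "pse_type2",
    "one_hot",
    "autocorrelation",
    "distance_pair",
    "AUTOCORRELATION_METHODS",
]

AUTOCORRELATION_METHODS = ("AC", "CC", "ACC", "MORAN", "GEARY", "NMBROTO")


def kmer_counts(seq: IndexArray, k: int, alphabet_size: int) -> np.ndarray:
    """Raw k-tuple counts over the |A|^k tuple indices."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if seq.length < k:
        raise DataFault(seq.seq_id, f"insufficient length for k={k} (L={seq.length})")
    tix = tuple_indices(seq.indices, k, alphabet_size)
    return np.bincount(tix, minlength=alphabet_size**k).astype(float)


@lru_cache(maxsize=64)
def _canonical_classes_cached(
    alphabet: tuple[str, ...], comp: tuple[int, ...], k: int
) -> tuple[np.ndarray, int]:
    size = len(alphabet)
    n_kmers = size**k
    comp_arr = np.array(comp, dtype=np.int64)
    # reverse-complement index of every k-mer, digit arithmetic base |A|
    digits = np.empty((n_kmers, k), dtype=np.int64)
    rem = np.arange(n_kmers)
    for pos in range(k - 1, -1, -1):
        digits[:, pos] = rem % size
        rem //= size
    rc_digits = comp_arr[digits][:, ::-1]
    rc = np.zeros(n_kmers, dtype=np.int64)
    for pos in range(k):
        rc = rc * size + rc_digits[:, pos]
    canon = np.minimum(np.arange(n_kmers), rc)
    classes, class_of = np.unique(canon, return_inverse=True)
    return class_of, len(classes)


def canonical_kmer_classes(seqtype: SequenceType, k: int) -> tuple[np.ndarray, int]:
    """Map each k-mer index to its canonical-class index.

    The canonical form of a k-mer is the lexicographically smaller of
    itself and its reverse complement; classes are ordered by their
    canonical k-mer index.  Returns ``(class_of_kmer, n_classes)``.
    """
    comp = tuple(int(i) for i in seqtype.complement_indices())
    return _canonical_classes_cached(seqtype.alphabet, comp, k)


def kmer_composition(
    seq: IndexArray,
    k: int,
    seqtype: SequenceType,
    collapse_revcomp: bool = False,
) -> np.ndarray:
    """Normalized k-tuple frequencies f_u = count(u)/(L−k+1).

    With ``collapse_revcomp`` the counts of a k-mer and its reverse
    complement are pooled onto the canonical class (requires a complement
    map); the output then has one entry per canonical class.  Entries
    always sum to 1.
    """
    counts = kmer_counts(seq, k, seqtype.size)
    if collapse_revcomp:
        class_of, n_classes = canonical_kmer_classes(seqtype, k)
        counts = np.bincount(class_of, weights=counts, minlength=n_classes)
    return counts / counts.sum()


def _lag_tuples(seq: IndexArray, lam: int, pair: PairCorrelationTable, size: int) -> np.ndarray:
    n = pair.tuple_size
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam > seq.length - n:
        raise DataFault(
            seq.seq_id,
            f"insufficient length for lambda={lam} with tuple size {n} (L={seq.length})",
        )
    return tuple_indices(seq.indices, n, size)


def theta_parallel(
    seq: IndexArray, lam: int, pair: PairCorrelationTable, alphabet_size: int
) -> np.ndarray:
    """Parallel-correlation tiers θ_1..θ_λ (averaged squared differences).

    θ_j averages Θ(D_i, D_{i+j}) over all N−j tuple pairs at lag j.  All
    tiers are non-negative; λ=0 yields an empty array.
    """
    tix = _lag_tuples(seq, lam, pair, alphabet_size)
    out = np.empty(lam, dtype=float)
    for j in range(1, lam + 1):
        out[j - 1] = pair.theta[tix[:-j], tix[j:]].mean()
    return out


def tau_series(
    seq: IndexArray, lam: int, pair: PairCorrelationTable, alphabet_size: int
) -> np.ndarray:
    """Series-correlation tiers τ_1..τ_{λΓ} (per-property products).

    Lag-major, property-minor ordering: τ_{(j−1)Γ+v} averages
    Π_v(D_i, D_{i+j}).  Entries may be negative; λ=0 yields an empty array.
    """
    tix = _lag_tuples(seq, lam, pair, alphabet_size)
    gamma = pair.n_properties
    out = np.empty(lam * gamma, dtype=float)
    for j in range(1, lam + 1):
        a, b = tix[:-j], tix[j:]
        for v in range(gamma):
            out[(j - 1) * gamma + v] = pair.products[v][a, b].mean()
    return out


def _pse(
    seq: IndexArray,
    k: int,
    lam: int,
    omega: float,
    pair: PairCorrelationTable,
    seqtype: SequenceType,
    tiers_fn,
) -> np.ndarray:
    if omega <= 0:
        raise ValueError("omega must be > 0")
    freqs = kmer_composition(seq, k, seqtype)
    tiers = tiers_fn(seq, lam, pair, seqtype.size)
    z = 1.0 + omega * tiers.sum()
    if abs(z) < 1e-12:
        raise DataFault(seq.seq_id, "degenerate pseudo-composition denominator (Z = 0)")
    return np.concatenate([freqs / z, omega * tiers / z])


def pse_type1(
    seq: IndexArray,
    k: int,
    lam: int,
    omega: float,
    pair: PairCorrelationTable,
    seqtype: SequenceType,
) -> np.ndarray:
    """Type-1 (parallel) pseudo k-tuple composition; dimension |A|^k + λ.

    All components are ≥ 0 and sum to 1.  With λ=0 this reduces exactly to
    :func:`kmer_composition`.
    """
    return _pse(seq, k, lam, omega, pair, seqtype, theta_parallel)


def pse_type2(
    seq: IndexArray,
    k: int,
    lam: int,
    omega: float,
    pair: PairCorrelationTable,
    seqtype: SequenceType,
) -> np.ndarray:
    """Type-2 (series/amphiphilic) pseudo composition; dimension |A|^k + λΓ.

    Components sum to 1 but pseudo components may be negative; Z = 1 + ωΣτ
    can vanish, which is reported as a degenerate-denominator data fault.
    """
    return _pse(seq, k, lam, omega, pair, seqtype, tau_series)


def one_hot(seq: IndexArray, target_length: int, alphabet_size: int) -> np.ndarray:
    """Position-wise indicator encoding padded to a fixed target length.

    Dimension target_length·|A|; position i (1-based), letter a sets entry
    (i−1)·|A| + idx(a).  Shorter sequences are zero-padded; longer ones
    are a data fault.
    """
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    if seq.length > target_length:
        raise DataFault(
            seq.seq_id,
            f"sequence length {seq.length} exceeds one-hot target length {target_length}",
        )
    out = np.zeros(target_length * alphabet_size, dtype=float)
    pos = np.arange(seq.length) * alphabet_size + seq.indices
    out[pos] = 1.0
    return out


def autocorrelation(
    seq: IndexArray,
    method: str,
    d_max: int,
    tables: Sequence[PropertyTable],
    seqtype: SequenceType,
) -> np.ndarray:
    """Property autocorrelation / cross-covariance descriptors.

    Over the N = L−n+1 tuple positions with normalized property values
    P_v(D_i) and sequence mean P̄_v:

    - ``AC``:      (1/(N−d)) Σ (P_v(D_i)−P̄_v)(P_v(D_{i+d})−P̄_v)
    - ``CC``:      same with two distinct properties v ≠ w
    - ``ACC``:     AC block then CC block
    - ``MORAN``:   AC divided by the (÷N) within-sequence variance
    - ``GEARY``:   (1/(2(N−d))) Σ (P_v(D_i)−P_v(D_{i+d}))² over the
      (÷(N−1)) variance
    - ``NMBROTO``: (1/(N−d)) Σ P_v(D_i)P_v(D_{i+d}) (un-centred)

    Lag-major ordering, then property (pair) index.  On zero-variance
    sequences the Moran and Geary ratios are defined as 0 rather than
    faulting (homopolymers are legitimate inputs).
    """
    method = method.upper()
    if method not in AUTOCORRELATION_METHODS:
        raise ValueError(f"unknown autocorrelation method {method!r}")
    if not tables:
        raise ValueError("at least one property table required")
    n = tables[0].tuple_size
    if any(t.tuple_size != n for t in tables):
        raise ValueError("mixed tuple sizes in property set")
    N = seq.length - n + 1
    if d_max < 1 or d_max > N - 1:
        raise DataFault(
            seq.seq_id,
            f"insufficient length for d_max={d_max} with tuple size {n} (L={seq.length})",
        )
    if method == "GEARY" and N < 2:
        raise DataFault(seq.seq_id, "Geary coefficient requires at least two tuples")

    tix = tuple_indices(seq.indices, n, seqtype.size)
    prof = np.stack([t.values_array(seqtype)[tix] for t in tables])  # (Γ, N)
    means = prof.mean(axis=1, keepdims=True)
    centred = prof - means
    gamma = prof.shape[0]

    def ac(v: int, w: int, d: int) -> float:
        return float(centred[v, :-d] @ centred[w, d:]) / (N - d)

    blocks: list[float] = []
    if method in ("AC", "ACC"):
        for d in range(1, d_max + 1):
            blocks.extend(ac(v, v, d) for v in range(gamma))
    if method in ("CC", "ACC"):
        for d in range(1, d_max + 1):
            blocks.extend(
                ac(v, w, d) for v in range(gamma) for w in range(gamma) if v != w
            )
    if method == "MORAN":
        var_n = (centred**2).mean(axis=1)  # ÷N
        for d in range(1, d_max + 1):
            blocks.extend(
                ac(v, v, d) / var_n[v] if var_n[v] > 0 else 0.0 for v in range(gamma)
            )
    if method == "GEARY":
        var_n1 = (centred**2).sum(axis=1) / (N - 1)
        for d in range(1, d_max + 1):
            for v in range(gamma):
                if var_n1[v] > 0:
                    num = float(((prof[v, :-d] - prof[v, d:]) ** 2).sum()) / (2 * (N - d))
                    blocks.append(num / var_n1[v])
                else:
                    blocks.append(0.0)
    if method == "NMBROTO":
        for d in range(1, d_max + 1):
            blocks.extend(float(prof[v, :-d] @ prof[v, d:]) / (N - d) for v in range(gamma))
    return np.array(blocks, dtype=float)


def distance_pair(seq: IndexArray, d_max: int, alphabet_size: int) -> np.ndarray:
    """Distance-pair (DR) descriptor.

    For each distance d = 1..d_max and ordered letter pair (a, b):
    frequency = count{i : R_i = a, R_{i+d} = b} / (L−d).  Distance-major
    ordering with pair index a·|A|+b; each distance block sums to 1.
    Dimension d_max·|A|².
    """
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    if d_max >= seq.length:
        raise DataFault(
            seq.seq_id, f"insufficient length for d_max={d_max} (L={seq.length})"
        )
    size = alphabet_size
    out = np.empty(d_max * size * size, dtype=float)
    for d in range(1, d_max + 1):
        pairs = seq.indices[:-d] * size + seq.indices[d:]
        counts = np.bincount(pairs, minlength=size * size).astype(float)
        out[(d - 1) * size * size : d * size * size] = counts / (seq.length - d)
    return out
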