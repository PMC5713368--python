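"""Descriptor kernels: worked examples, invariants, and oracle equivalence.

Every kernel is checked against the independent naive loop implementation
in ``reference_impl``; this certifies that the pre-computed pair-table
fast path changes nothing numerically.
"""

import numpy as np
import pytest

from seqdesc.alphabet import DataFault, SequenceType
from seqdesc.kernels import (
    AUTOCORRELATION_METHODS,
    autocorrelation,
    distance_pair,
    kmer_composition,
    one_hot,
    pse_type1,
    pse_type2,
    tau_series,
    theta_parallel,
)
from seqdesc.properties import build_pair_tables
from seqdesc.synthetic import toy_property_table

import reference_impl as ref


def enc(seqtype, letters, seq_id="s"):
    return seqtype.encode(seq_id, letters)


class TestKmerComposition:
    def test_homopolymer_protein(self, prot):
        vec = kmer_composition(enc(prot, "AAAA"), 1, prot)
        assert vec[0] == 1.0 and vec[1:].sum() == 0

    def test_overlapping_dimers(self, dna):
        vec = kmer_composition(enc(dna, "ACGT"), 2, dna)
        # AC=1, CG=6, GT=11 each 1/3
        assert vec[[1, 6, 11]] == pytest.approx([1 / 3] * 3)
        assert vec.sum() == pytest.approx(1.0)

    def test_revcomp_collapse_k1(self, dna):
        vec = kmer_composition(enc(dna, "ACGT"), 1, dna, collapse_revcomp=True)
        assert vec.shape == (2,)  # classes {A/T}, {C/G}
        assert vec == pytest.approx([0.5, 0.5])

    def test_collapse_matches_bruteforce(self, dna, rng):
        for k in (1, 2, 3):
            for _ in range(10):
                letters = "".join(
                    np.array(list("ACGT"))[rng.integers(0, 4, int(rng.integers(5, 40)))]
                )
                got = kmer_composition(enc(dna, letters), k, dna, collapse_revcomp=True)
                comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
                expected = ref.naive_kmer_collapsed(letters, "ACGT", k, comp)
                assert got == pytest.approx(expected, abs=1e-12)

    def test_too_short_is_fault(self, dna):
        with pytest.raises(DataFault, match="insufficient length"):
            kmer_composition(enc(dna, "AC"), 3, dna)


class TestCorrelationTiers:
    def test_homopolymer_theta_zero(self, ab_type, ab_h1):
        pair = build_pair_tables([ab_h1], ab_type)
        seq = enc(ab_type, "AAAAA")
        assert theta_parallel(seq, 2, pair, 2) == pytest.approx([0.0, 0.0])

    def test_single_pair_theta(self, ab_type, ab_h1):
        pair = build_pair_tables([ab_h1], ab_type)
        assert theta_parallel(enc(ab_type, "AB"), 1, pair, 2) == pytest.approx([4.0])

    def test_alternating_lags(self, ab_type, ab_h1):
        pair = build_pair_tables([ab_h1], ab_type)
        theta = theta_parallel(enc(ab_type, "ABAB"), 2, pair, 2)
        assert theta == pytest.approx([4.0, 0.0])

    def test_tau_two_properties(self, ab_type, ab_h1, ab_h2):
        pair = build_pair_tables([ab_h1, ab_h2], ab_type)
        tau = tau_series(enc(ab_type, "AB"), 1, pair, 2)
        assert tau == pytest.approx([-1.0, -1.0])

    def test_tau_homopolymer_does_not_vanish(self, ab_type, ab_h1):
        pair = build_pair_tables([ab_h1], ab_type)
        tau = tau_series(enc(ab_type, "AAAA"), 1, pair, 2)
        assert tau == pytest.approx([1.0])

    def test_lambda_zero_empty(self, ab_type, ab_h1):
        pair = build_pair_tables([ab_h1], ab_type)
        assert tau_series(enc(ab_type, "ABAB"), 0, pair, 2).size == 0
        assert theta_parallel(enc(ab_type, "ABAB"), 0, pair, 2).size == 0

    def test_lambda_exceeding_length_is_fault(self, ab_type, ab_h1):
        pair = build_pair_tables([ab_h1], ab_type)
        with pytest.raises(DataFault, match="insufficient length"):
            theta_parallel(enc(ab_type, "AB"), 2, pair, 2)

    def test_reversal_invariance_n1(self, prot, rng):
        # symmetric Θ/Π and symmetric lag pairing make tiers reversal-invariant
        tables = [toy_property_table(prot, 1, rng, f"p{i}") for i in range(2)]
        pair = build_pair_tables(tables, prot)
        for _ in range(20):
            letters = "".join(
                np.array(list(prot.alphabet))[rng.integers(0, 20, 15)]
            )
            fwd, rev = enc(prot, letters), enc(prot, letters[::-1])
            assert theta_parallel(fwd, 3, pair, 20) == pytest.approx(
                theta_parallel(rev, 3, pair, 20), abs=1e-12
            )
            assert tau_series(fwd, 3, pair, 20) == pytest.approx(
                tau_series(rev, 3, pair, 20), abs=1e-12
            )


class TestPseudoComposition:
    def test_type1_worked_example(self, ab_type, ab_h1):
        # f = (0.5, 0.5), theta_1 = 4, Z = 1 + 0.5*4 = 3
        pair = build_pair_tables([ab_h1], ab_type)
        vec = pse_type1(enc(ab_type, "AB"), 1, 1, 0.5, pair, ab_type)
        assert vec == pytest.approx([1 / 6, 1 / 6, 2 / 3])

    def test_type1_homopolymer_reduces_to_composition(self, prot):
        from seqdesc.properties import PropertyRegistry

        props = PropertyRegistry()
        pair = build_pair_tables(
            props.get_set(["hydrophobicity", "hydrophilicity", "side-chain-mass"]), prot
        )
        vec = pse_type1(enc(prot, "AAAAAA"), 1, 3, 0.05, pair, prot)
        assert vec[0] == pytest.approx(1.0)
        assert vec[1:] == pytest.approx(np.zeros(22))

    def test_type2_worked_example(self, ab_type, ab_h1, ab_h2):
        # tau = (-1, -1), Z = 1 + 0.1*(-2) = 0.8
        pair = build_pair_tables([ab_h1, ab_h2], ab_type)
        vec = pse_type2(enc(ab_type, "AB"), 1, 1, 0.1, pair, ab_type)
        assert vec == pytest.approx([0.625, 0.625, -0.125, -0.125])

    def test_type2_degenerate_denominator(self, ab_type, ab_h1, ab_h2):
        # Z = 1 + 0.5*(-2) = 0
        pair = build_pair_tables([ab_h1, ab_h2], ab_type)
        with pytest.raises(DataFault, match="degenerate"):
            pse_type2(enc(ab_type, "AB"), 1, 1, 0.5, pair, ab_type)

    def test_lambda_zero_reduction_exact(self, dna, rng):
        pair = build_pair_tables([toy_property_table(dna, 2, rng)], dna)
        for _ in range(10):
            letters = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 20)])
            seq = enc(dna, letters)
            comp = kmer_composition(seq, 2, dna)
            assert np.array_equal(pse_type1(seq, 2, 0, 0.05, pair, dna), comp)
            assert np.array_equal(pse_type2(seq, 2, 0, 0.05, pair, dna), comp)


class TestOneHot:
    def test_exact_length(self, dna):
        vec = one_hot(enc(dna, "AC"), 2, 4)
        assert list(vec) == [1, 0, 0, 0, 0, 1, 0, 0]

    def test_zero_padding(self, dna):
        vec = one_hot(enc(dna, "A"), 2, 4)
        assert list(vec) == [1, 0, 0, 0, 0, 0, 0, 0]

    def test_overflow_is_fault(self, dna):
        with pytest.raises(DataFault, match="exceeds"):
            one_hot(enc(dna, "ACG"), 2, 4)


class TestAutocorrelation:
    def test_two_letter_worked_examples(self, ab_type, ab_h1):
        seq = enc(ab_type, "AB")
        tables = [ab_h1]
        assert autocorrelation(seq, "AC", 1, tables, ab_type) == pytest.approx([-1.0])
        assert autocorrelation(seq, "MORAN", 1, tables, ab_type) == pytest.approx([-1.0])
        assert autocorrelation(seq, "GEARY", 1, tables, ab_type) == pytest.approx([1.0])
        assert autocorrelation(seq, "NMBROTO", 1, tables, ab_type) == pytest.approx([-1.0])

    def test_homopolymer_zero_variance(self, ab_type, ab_h1):
        seq = enc(ab_type, "AAAA")
        assert autocorrelation(seq, "AC", 2, [ab_h1], ab_type) == pytest.approx([0, 0])
        # Moran/Geary define 0/0 as 0 instead of faulting
        assert autocorrelation(seq, "MORAN", 2, [ab_h1], ab_type) == pytest.approx([0, 0])
        assert autocorrelation(seq, "GEARY", 2, [ab_h1], ab_type) == pytest.approx([0, 0])

    def test_cc_dimension(self, ab_type, ab_h1, ab_h2):
        vec = autocorrelation(enc(ab_type, "ABBA"), "CC", 1, [ab_h1, ab_h2], ab_type)
        assert vec.shape == (2,)  # Γ(Γ−1) per lag

    def test_insufficient_length_fault(self, ab_type, ab_h1):
        with pytest.raises(DataFault):
            autocorrelation(enc(ab_type, "AB"), "AC", 2, [ab_h1], ab_type)


class TestDistancePair:
    def test_single_pair(self, ab_type):
        vec = distance_pair(enc(ab_type, "AB"), 1, 2)
        assert list(vec) == [0, 1, 0, 0]  # ordering AA, AB, BA, BB

    def test_homopolymer_blocks(self, ab_type):
        vec = distance_pair(enc(ab_type, "AAA"), 2, 2)
        assert list(vec) == [1, 0, 0, 0, 1, 0, 0, 0]

    def test_alternating(self, ab_type):
        vec = distance_pair(enc(ab_type, "ABAB"), 1, 2)
        assert vec == pytest.approx([0, 2 / 3, 1 / 3, 0])

    def test_each_distance_block_sums_to_one(self, dna, rng):
        letters = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 30)])
        vec = distance_pair(enc(dna, letters), 3, 4)
        for d in range(3):
            assert vec[d * 16 : (d + 1) * 16].sum() == pytest.approx(1.0)

    def test_too_short_fault(self, ab_type):
        with pytest.raises(DataFault):
            distance_pair(enc(ab_type, "AB"), 2, 2)


class TestOracleEquivalence:
    """Randomized cross-check of every kernel against the naive loops."""

    def _random_case(self, rng, alphabet="ACGT"):
        seqtype = SequenceType(
            "T", tuple(alphabet),
            {"A": "T", "T": "A", "C": "G", "G": "C"} if alphabet == "ACGT" else None,
        )
        length = int(rng.integers(5, 51))
        letters = "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), length)])
        return seqtype, letters

    @pytest.mark.parametrize("tuple_size", [1, 2])
    def test_theta_tau_pse_match_naive(self, rng, tuple_size):
        for _ in range(30):
            seqtype, letters = self._random_case(rng)
            tables = [
                toy_property_table(seqtype, tuple_size, rng, f"p{i}") for i in range(2)
            ]
            norm = [t.normalized for t in tables]
            pair = build_pair_tables(tables, seqtype)
            seq = enc(seqtype, letters)
            lam = int(rng.integers(1, min(4, len(letters) - tuple_size) + 1))
            omega = float(rng.uniform(0.01, 0.5))
            assert theta_parallel(seq, lam, pair, 4) == pytest.approx(
                ref.naive_theta(letters, norm, lam, tuple_size), abs=1e-12
            )
            assert tau_series(seq, lam, pair, 4) == pytest.approx(
                ref.naive_tau(letters, norm, lam, tuple_size), abs=1e-12
            )
            k = int(rng.integers(1, 3))
            assert pse_type1(seq, k, lam, omega, pair, seqtype) == pytest.approx(
                ref.naive_pse1(letters, "ACGT", k, lam, omega, norm, tuple_size),
                abs=1e-12,
            )
            assert pse_type2(seq, k, lam, omega, pair, seqtype) == pytest.approx(
                ref.naive_pse2(letters, "ACGT", k, lam, omega, norm, tuple_size),
                abs=1e-12,
            )

    @pytest.mark.parametrize("method", AUTOCORRELATION_METHODS)
    def test_autocorrelation_matches_naive(self, rng, method):
        for _ in range(20):
            seqtype, letters = self._random_case(rng)
            n = int(rng.integers(1, 3))
            tables = [toy_property_table(seqtype, n, rng, f"p{i}") for i in range(2)]
            norm = [t.normalized for t in tables]
            N = len(letters) - n + 1
            d_max = int(rng.integers(1, min(4, N - 1) + 1))
            seq = enc(seqtype, letters)
            assert autocorrelation(seq, method, d_max, tables, seqtype) == pytest.approx(
                ref.naive_autocorrelation(letters, method, d_max, norm, n), abs=1e-12
            )

    def test_kmer_onehot_distance_match_naive(self, rng):
        for _ in range(30):
            seqtype, letters = self._random_case(rng)
            seq = enc(seqtype, letters)
            k = int(rng.integers(1, 4))
            assert kmer_composition(seq, k, seqtype) == pytest.approx(
                ref.naive_kmer(letters, "ACGT", k), abs=1e-12
            )
            d_max = int(rng.integers(1, min(4, len(letters) - 1) + 1))
            assert distance_pair(seq, d_max, 4) == pytest.approx(
                ref.naive_distance_pair(letters, "ACGT", d_max), abs=1e-12
            )
            target = len(letters) + int(rng.integers(0, 5))
            assert one_hot(seq, target, 4) == pytest.approx(
                ref.naive_one_hot(letters, "ACGT", target), abs=1e-12
            )

    def test_sum_to_one_and_nonnegativity(self, rng):
        for _ in range(50):
            seqtype, letters = self._random_case(rng)
            seq = enc(seqtype, letters)
            tables = [toy_property_table(seqtype, 1, rng, f"p{i}") for i in range(2)]
            pair = build_pair_tables(tables, seqtype)
            lam = int(rng.integers(0, 4))
            comp = kmer_composition(seq, 2, seqtype)
            p1 = pse_type1(seq, 1, lam, 0.05, pair, seqtype)
            p2 = pse_type2(seq, 1, lam, 0.05, pair, seqtype)
            for vec in (comp, p1, p2):
                assert abs(vec.sum() - 1) < 1e-9
            assert np.all(comp >= 0) and np.all(p1 >= 0)
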