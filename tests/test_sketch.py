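"""Canonical k-mer extraction, bottom sketching and the Mash distance."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from divm3 import (
    SketchParams,
    Sketch,
    build_sketch,
    extract_canonical_kmers,
    jaccard_exact,
    mash_distance,
    mash_distance_from_jaccard,
    sketch_sequence,
)
from divm3._kmers import canonical, revcomp

from conftest import random_dna

dna = st.text(alphabet="ACGT", min_size=8, max_size=200)


def params(k=3, s=None, **kw):
    return SketchParams(k=k, s=s, **kw)


class TestCanonicalKmers:
    @pytest.mark.parametrize(
        "seq,k,expected",
        [
            ("ACGT", 3, {"ACG"}),  # revcomp(CGT) = ACG
            ("AAAAA", 3, {"AAA"}),  # canonical of AAA/TTT is AAA
            ("ACGNACG", 3, {"ACG"}),  # windows containing N skipped
            ("AC", 3, set()),  # shorter than k
            ("acgt", 3, {"ACG"}),  # soft-masked folds to uppercase
        ],
    )
    def test_hand_enumerated_examples(self, seq, k, expected):
        assert extract_canonical_kmers(seq, params(k)) == expected

    def test_softmask_policy_off_skips_lowercase(self):
        p = SketchParams(k=3, s=None, fold_lowercase=False)
        assert extract_canonical_kmers("acgtACGTA", p) == extract_canonical_kmers(
            "NNNNACGTA", p
        )

    def test_invalid_character_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            extract_canonical_kmers("AC!GT", params())

    def test_iupac_ambiguity_letters_skip_windows(self):
        assert extract_canonical_kmers("ACGRACG", params(3)) == {"ACG"}

    @given(dna)
    def test_strand_symmetry(self, seq):
        p = params(5)
        assert extract_canonical_kmers(seq, p) == extract_canonical_kmers(
            revcomp(seq), p
        )

    @given(dna)
    def test_matches_naive_python_enumeration(self, seq):
        k = 5
        naive = {
            canonical(seq[i : i + k])
            for i in range(len(seq) - k + 1)
        }
        assert extract_canonical_kmers(seq, params(k)) == naive


class TestBuildSketch:
    def test_small_input_keeps_everything(self):
        kmers = extract_canonical_kmers(random_dna(100, 1), params(7))
        sk = build_sketch(kmers, "x", SketchParams(k=7, s=5000))
        assert len(sk) == sk.total_distinct == len(kmers)

    def test_bottom_s_equals_sorted_all_hashes(self):
        p_all = SketchParams(k=7, s=None)
        p3 = SketchParams(k=7, s=3)
        kmers = extract_canonical_kmers(random_dna(60, 2), params(7))
        full = build_sketch(kmers, "x", p_all)
        small = build_sketch(kmers, "x", p3)
        assert np.array_equal(small.hashes, np.sort(full.hashes)[:3])

    def test_deterministic(self):
        kmers = extract_canonical_kmers(random_dna(200, 3), params(9))
        a = build_sketch(kmers, "x", SketchParams(k=9, s=10))
        b = build_sketch(kmers, "x", SketchParams(k=9, s=10))
        assert np.array_equal(a.hashes, b.hashes)

    def test_empty_kmer_set_errors(self):
        with pytest.raises(ValueError, match="no valid k-mers"):
            build_sketch(set(), "x", params())

    def test_all_n_sequence_errors(self):
        with pytest.raises(ValueError, match="no valid k-mers"):
            sketch_sequence("N" * 50, "x", SketchParams(k=7, s=10))

    @given(dna)
    def test_fast_path_matches_string_path(self, seq):
        p = SketchParams(k=5, s=10)
        via_strings = build_sketch(extract_canonical_kmers(seq, p), "x", p)
        via_array = sketch_sequence(seq, "x", p)
        assert np.array_equal(via_strings.hashes, via_array.hashes)
        assert via_strings.total_distinct == via_array.total_distinct


class TestSketchParams:
    @pytest.mark.parametrize("k", [2, 4, 1, 33])
    def test_even_or_out_of_range_k_rejected(self, k):
        with pytest.raises(ValueError):
            SketchParams(k=k)

    def test_zero_sketch_size_rejected(self):
        with pytest.raises(ValueError):
            SketchParams(s=0)


class TestMashDistance:
    def test_identity_is_exactly_zero(self):
        sk = sketch_sequence(random_dna(500, 4), "x", SketchParams(k=11, s=100))
        rec = mash_distance(sk, sk)
        assert rec.distance == 0.0 and rec.jaccard_est == 1.0

    def test_disjoint_sketches_capped_at_one(self):
        p = SketchParams(k=3, s=None)
        a = sketch_sequence("AAAAAAAA", "a", p)
        b = sketch_sequence("CCCCCCCC", "b", p)
        rec = mash_distance(a, b)
        assert rec.jaccard_est == 0.0 and rec.distance == 1.0 and rec.capped

    def test_known_jaccard_third_gives_ln2_over_k(self):
        # constructed sketches sharing 2 of 6 union hashes: j = 1/3,
        # D = -(1/21) ln(2(1/3)/(4/3)) = ln(2)/21
        p = SketchParams(k=21, s=None)
        a = Sketch("a", p, np.array([1, 2, 3, 4], dtype=np.uint64), 4)
        b = Sketch("b", p, np.array([3, 4, 5, 6], dtype=np.uint64), 4)
        rec = mash_distance(a, b)
        assert rec.jaccard_est == pytest.approx(1 / 3)
        assert rec.distance == pytest.approx(math.log(2) / 21, abs=1e-12)

    def test_symmetry(self):
        p = SketchParams(k=7, s=50)
        a = sketch_sequence(random_dna(300, 5), "a", p)
        b = sketch_sequence(random_dna(300, 6), "b", p)
        assert mash_distance(a, b).distance == mash_distance(b, a).distance

    def test_incompatible_params_rejected(self):
        a = sketch_sequence(random_dna(100, 7), "a", SketchParams(k=7, s=10))
        b = sketch_sequence(random_dna(100, 7), "b", SketchParams(k=9, s=10))
        with pytest.raises(ValueError, match="incomparable"):
            mash_distance(a, b)
        c = sketch_sequence(
            random_dna(100, 7), "c", SketchParams(k=7, s=10, hash_seed=1)
        )
        with pytest.raises(ValueError, match="incomparable"):
            mash_distance(a, c)


class TestJaccardExact:
    def test_identity(self):
        seq = random_dna(400, 8)
        assert jaccard_exact(seq, seq, params(7)) == 1.0

    def test_provably_disjoint_sets(self):
        assert jaccard_exact("A" * 30, "C" * 30, params(3)) == 0.0

    def test_hand_enumerated_pair(self):
        # ACGTACG 5-mers: ACGTA, CGTAC->CGTAC vs GTACG->CGTAC, canonical sets
        # enumerated with the naive oracle below
        a, b = "ACGTACG", "ACGTTGC"
        k = 5
        sa = {canonical(a[i : i + k]) for i in range(len(a) - k + 1)}
        sb = {canonical(b[i : i + k]) for i in range(len(b) - k + 1)}
        expected = len(sa & sb) / len(sa | sb)
        assert jaccard_exact(a, b, params(5)) == pytest.approx(expected)

    def test_oracle_equivalence_with_exhaustive_sketch(self):
        # with s >= |union| the sketch estimator reproduces the exact
        # Jaccard to machine precision (the effectively exhaustive sketch)
        p = SketchParams(k=11, s=None)
        for seed in range(5):
            a = random_dna(2000, 100 + seed)
            b = random_dna(2000, 200 + seed, gc=0.3)
            rec = mash_distance(
                sketch_sequence(a, "a", p), sketch_sequence(b, "b", p)
            )
            assert rec.jaccard_est == pytest.approx(
                jaccard_exact(a, b, p), abs=1e-12
            )
            assert rec.distance == pytest.approx(
                mash_distance_from_jaccard(rec.jaccard_est, 11), abs=1e-12
            )


def test_divergence_monotone_in_substitution_rate():
    """Mean Mash distance increases with the substitution rate."""
    from divm3 import evolve_sequence

    p = SketchParams(s=2000)
    means = []
    for rate in (0.01, 0.05):
        ds = []
        for seed in range(3):
            anc = random_dna(100_000, 900 + seed)
            der = evolve_sequence(anc, rate, seed=seed)
            ds.append(
                mash_distance(
                    sketch_sequence(anc, "a", p), sketch_sequence(der, "d", p)
                ).distance
            )
        means.append(np.mean(ds))
    assert means[0] < means[1]
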