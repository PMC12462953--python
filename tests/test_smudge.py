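"""Heterozygous k-mer-pair detection, coverage estimation and genotyping."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from divm3 import (
    Haplotype,
    SimParams,
    classify_genotypes,
    count_kmers_from_reads,
    depth_cutoff,
    estimate_haploid_coverage,
    evolve_sequence,
    find_het_pairs,
    random_genome,
    simulate_reads,
)
from divm3.smudge import HetKmerPair, KmerCounts
from divm3._kmers import canonical

from conftest import random_dna


def make_pairs(spec):
    """Synthetic pairs from (total, ratio) tuples."""
    out = []
    for t, r in spec:
        covB = int(round(t * r))
        out.append(HetKmerPair("A" * 21, "C" * 21, t - covB, covB))
    return out


class TestCounting:
    def test_single_read_both_windows_canonicalize(self):
        counts = count_kmers_from_reads(["ACGT"], k=3)
        assert counts.to_dict() == {"ACG": 2}

    def test_counts_additive_over_duplicate_reads(self):
        seq = random_dna(100, 11)
        once = count_kmers_from_reads([seq], k=7)
        twice = count_kmers_from_reads([seq, seq], k=7)
        assert np.array_equal(twice.kmers, once.kmers)
        assert np.array_equal(twice.counts, 2 * once.counts)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError, match="no reads"):
            count_kmers_from_reads([], k=7)

    def test_simulated_coverage_recovers_modal_depth(self):
        genome = random_genome(SimParams(n_chrom=1, chrom_len=10_000, seed=12))
        reads = simulate_reads(
            [Haplotype("h", genome["chr1"])], coverage_per_copy=10,
            read_len=100, error_rate=0.0, seed=13,
        )
        counts = count_kmers_from_reads((s for _n, s in reads), k=21)
        hist = np.bincount(counts.counts)
        modal = int(np.argmax(hist))
        # k-mer depth = base depth * (read_len-k+1)/read_len = 8
        assert abs(modal - 8) <= 1


class TestDepthCutoff:
    def test_user_cutoff_passthrough(self):
        counts = count_kmers_from_reads([random_dna(100, 1)], k=7)
        assert depth_cutoff(counts, 20) == 20

    def test_bimodal_histogram_locates_error_minimum(self):
        # error peak at depth 1-2, genomic peak at 30
        rng = np.random.default_rng(4)
        kmers = np.arange(5000, dtype=np.uint64)
        counts = np.concatenate(
            [
                rng.integers(1, 3, size=3000),
                rng.poisson(30, size=2000).clip(min=1),
            ]
        )
        L = depth_cutoff(KmerCounts(21, kmers, counts.astype(np.int64)))
        assert 3 <= L <= 15

    def test_monotone_histogram_is_an_error(self):
        kmers = np.arange(700, dtype=np.uint64)
        counts = np.repeat([1, 2, 3, 4], [400, 200, 80, 20]).astype(np.int64)
        with pytest.raises(ValueError, match="monotone"):
            depth_cutoff(KmerCounts(21, kmers, counts))

    def test_error_reads_simulation(self):
        genome = random_genome(SimParams(n_chrom=1, chrom_len=20_000, seed=3))
        reads = simulate_reads(
            [Haplotype("h", genome["chr1"])], coverage_per_copy=30,
            read_len=100, error_rate=0.01, seed=5,
        )
        counts = count_kmers_from_reads((s for _n, s in reads), k=21)
        assert 3 <= depth_cutoff(counts) <= 15


class TestFindHetPairs:
    def small_counts(self, d, k=3):
        return KmerCounts.from_dict(d, k)

    def test_one_snp_pair_found_with_coverages(self):
        pairs = find_het_pairs(self.small_counts({"AAA": 30, "AAC": 28}), L=20)
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.covA, p.covB) == (30, 28)
        assert {p.kmer_major, p.kmer_minor} == {"AAA", "AAC"}

    def test_distant_kmers_not_paired(self):
        assert find_het_pairs(self.small_counts({"AAA": 30, "CCC": 30}), L=20) == []

    def test_below_cutoff_members_excluded(self):
        assert find_het_pairs(self.small_counts({"AAA": 30, "AAC": 10}), L=20) == []

    def test_kmer_in_multiple_pairs_dropped(self):
        counts = self.small_counts({"AAA": 30, "AAC": 28, "AAG": 26})
        assert find_het_pairs(counts, L=20) == []

    @given(st.integers(0, 4**8 - 1), st.integers(0, 7), st.integers(1, 3))
    def test_pair_found_regardless_of_canonical_orientation(self, code, pos, shift):
        """A one-SNP mutant is always detected, whichever strand each
        canonical representative happens to come from."""
        k = 8 + 1  # odd k
        bases = "ACGT"
        kmer = "".join(bases[(code >> (2 * i)) & 3] for i in range(8)) + "A"
        old = kmer[pos]
        new = bases[(bases.index(old) + shift) % 4]
        mutant = kmer[:pos] + new + kmer[pos + 1 :]
        c1, c2 = canonical(kmer), canonical(mutant)
        if c1 == c2:  # palindromic edge: mutant collapses to same canonical
            return
        pairs = find_het_pairs(KmerCounts.from_dict({c1: 30, c2: 25}, k), L=20)
        assert len(pairs) == 1
        assert {pairs[0].kmer_major, pairs[0].kmer_minor} == {c1, c2}

    def test_heterozygous_diploid_pair_count_tracks_snp_count(self):
        genome = random_genome(SimParams(n_chrom=1, chrom_len=50_000, seed=31))
        hap1 = genome["chr1"]
        hap2 = evolve_sequence(hap1, 0.001, seed=32)  # ~50 SNPs
        reads = simulate_reads(
            [Haplotype("a", hap1), Haplotype("b", hap2)], coverage_per_copy=20,
            read_len=100, error_rate=0.0, seed=33,
        )
        counts = count_kmers_from_reads((s for _n, s in reads), k=21)
        pairs = find_het_pairs(counts, L=10)
        n_snp = sum(a != b for a, b in zip(hap1, hap2))
        # every isolated SNP yields ~k pairs (one per overlapping window)
        assert pairs and abs(len(pairs) - 21 * n_snp) / (21 * n_snp) < 0.25

    def test_homozygous_genome_yields_no_pairs(self):
        genome = random_genome(SimParams(n_chrom=1, chrom_len=30_000, seed=35))
        reads = simulate_reads(
            [Haplotype("h", genome["chr1"], 2)], coverage_per_copy=15,
            read_len=100, error_rate=0.0, seed=36,
        )
        counts = count_kmers_from_reads((s for _n, s in reads), k=21)
        assert len(find_het_pairs(counts, L=10)) <= 2

    def test_reported_pair_invariants(self):
        genome = random_genome(SimParams(n_chrom=1, chrom_len=30_000, seed=41))
        hap2 = evolve_sequence(genome["chr1"], 0.002, seed=42)
        reads = simulate_reads(
            [Haplotype("a", genome["chr1"]), Haplotype("b", hap2)],
            coverage_per_copy=15, read_len=100, error_rate=0.002, seed=43,
        )
        counts = count_kmers_from_reads((s for _n, s in reads), k=21)
        L = 8
        for p in find_het_pairs(counts, L):
            assert p.covB <= p.covA
            assert p.covA >= L and p.covB >= L
            assert 0 < p.ratio <= 0.5
            assert p.total >= 2 * L
            from divm3._kmers import revcomp

            diff = sum(a != b for a, b in zip(p.kmer_major, p.kmer_minor))
            diff_rc = sum(
                a != b for a, b in zip(p.kmer_major, revcomp(p.kmer_minor))
            )
            # Hamming distance exactly 1 in a consistent orientation
            assert 1 in (diff, diff_rc)


class TestCoverageEstimate:
    def test_single_ab_smudge(self):
        assert estimate_haploid_coverage(
            make_pairs([(30, 0.5)] * 50), L=10, max_ploidy=4
        ) == pytest.approx(15.0)

    def test_lone_4c_smudge_reads_as_diploid(self):
        # a single smudge at total 60 is indistinguishable from AB at c=30;
        # the smallest-multiplicity reading wins by design
        assert estimate_haploid_coverage(
            make_pairs([(60, 0.5)] * 50), L=10, max_ploidy=4
        ) == pytest.approx(30.0)

    def test_two_smudges_pin_coverage(self):
        pairs = make_pairs([(30, 0.5)] * 50 + [(60, 0.5)] * 50)
        assert estimate_haploid_coverage(pairs, L=10) == pytest.approx(15.0, rel=0.1)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            estimate_haploid_coverage(make_pairs([(30, 0.5)] * 3))


class TestClassification:
    def test_exact_centres(self):
        c = 15
        assert classify_genotypes(make_pairs([(4 * c, 0.5)] * 10), c).modal_genotype == "AABB"
        assert classify_genotypes(make_pairs([(2 * c, 0.5)] * 10), c).modal_genotype == "AB"
        assert classify_genotypes(make_pairs([(3 * c, 1 / 3)] * 10), c).modal_genotype == "AAB"

    def test_proportions_sum_to_one(self):
        summary = classify_genotypes(
            make_pairs([(30, 0.5)] * 6 + [(60, 0.5)] * 3 + [(45, 0.33)] * 1), 15
        )
        assert sum(summary.proportions.values()) == pytest.approx(1.0, abs=1e-9)
        assert summary.modal_genotype == "AB"

    def test_invalid_coverage_rejected(self):
        with pytest.raises(ValueError):
            classify_genotypes(make_pairs([(30, 0.5)] * 5), 0.0)


class TestEndToEndPloidy:
    def _analyze(self, haps, seed, cov=15):
        reads = simulate_reads(
            haps, coverage_per_copy=cov, read_len=100, error_rate=0.005, seed=seed
        )
        from divm3 import run_smudge_analysis

        summary, pairs, L = run_smudge_analysis((s for _n, s in reads), k=21)
        return summary

    def test_ab_diploid_modal_ab(self):
        genome = random_genome(SimParams(n_chrom=1, chrom_len=100_000, seed=3))
        hap2 = evolve_sequence(genome["chr1"], 0.001, seed=4)
        summary = self._analyze(
            [Haplotype("a", genome["chr1"]), Haplotype("b", hap2)], seed=5
        )
        assert summary.modal_genotype == "AB"
        c_true = 15 * 0.8 * (1 - 0.005) ** 21
        assert summary.haploid_coverage == pytest.approx(c_true, rel=0.10)

    def test_doubling_depth_doubles_coverage_same_genotype(self):
        genome = random_genome(SimParams(n_chrom=1, chrom_len=100_000, seed=23))
        hap2 = evolve_sequence(genome["chr1"], 0.001, seed=24)
        haps = [Haplotype("a", genome["chr1"]), Haplotype("b", hap2)]
        s1 = self._analyze(haps, seed=25, cov=12)
        s2 = self._analyze(haps, seed=25, cov=24)
        assert s1.modal_genotype == s2.modal_genotype == "AB"
        assert s2.haploid_coverage == pytest.approx(2 * s1.haploid_coverage, rel=0.10)
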