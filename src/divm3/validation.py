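"""Self-contained validation scenarios for the whole pipeline.

Each function simulates data under a stated study condition, runs the
relevant part of the pipeline, and returns the measured quantities. They are
used both by the test suite and by ``scripts/acceptance.py``; all randomness
flows from the single seed argument.

Problem sizes (chromosome counts and lengths, replicate counts, coverages)
are chosen so every scenario runs in minutes on one CPU while keeping the
statistical properties it checks well away from sampling noise.
"""

from __future__ import annotations

import numpy as np

from .pairing import distance_matrix, infer_homoeolog_pairs
from .partition import assign_subgenomes
from .sim import (
    Haplotype,
    SimParams,
    evolve_sequence,
    insert_repeats,
    make_allotetraploid,
    mask_intervals,
    random_genome,
    simulate_reads,
)
from .sketch import (
    SketchParams,
    jaccard_exact,
    mash_distance,
    mash_distance_from_jaccard,
    sketch_sequence,
)
from .smudge import run_smudge_analysis

_SEED_CAP = 2**31 - 1


def _subseeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.default_rng(seed).integers(0, _SEED_CAP, n)]


def sketch_oracle_check(seed: int, n_pairs: int = 50) -> dict[str, float]:
    """Exhaustive-sketch estimates vs the brute-force Jaccard oracle.

    Random 1-10 kb sequence pairs of mixed GC content, half of them related
    (one is a mutated copy of the other) so the Jaccard index spans (0, 1).
    With the sketch retaining every hash the estimator must reproduce the
    exact Jaccard, and the distance must match a direct evaluation of the
    Mash transform, to machine precision.
    """
    rng = np.random.default_rng(seed)
    p = SketchParams(k=21, s=None)
    max_j_err = 0.0
    max_d_err = 0.0
    for i in range(n_pairs):
        n = int(rng.integers(1_000, 10_001))
        gc = float(rng.uniform(0.25, 0.65))
        sp = SimParams(n_chrom=1, chrom_len=n, gc=gc, seed=int(rng.integers(_SEED_CAP)))
        a = random_genome(sp)["chr1"]
        if i % 2 == 0:
            b = evolve_sequence(a, float(rng.uniform(0.001, 0.1)),
                                seed=int(rng.integers(_SEED_CAP)))
        else:
            sp2 = SimParams(n_chrom=1, chrom_len=n, gc=gc,
                            seed=int(rng.integers(_SEED_CAP)))
            b = random_genome(sp2)["chr1"]
        rec = mash_distance(sketch_sequence(a, "a", p), sketch_sequence(b, "b", p))
        j_exact = jaccard_exact(a, b, p)
        max_j_err = max(max_j_err, abs(rec.jaccard_est - j_exact))
        max_d_err = max(
            max_d_err,
            abs(rec.distance - mash_distance_from_jaccard(rec.jaccard_est, p.k)),
        )
    return {"max_jaccard_error": max_j_err, "max_distance_error": max_d_err, "n": n_pairs}


def rate_recovery(
    seed: int,
    rates: tuple[float, ...] = (0.01, 0.02, 0.05),
    n_replicates: int = 10,
    length: int = 1_000_000,
) -> dict:
    """Mash distance as an estimator of the substitution rate.

    1 Mb sequences, k=21, substitutions only: the mean estimated distance
    over replicates should match the simulated per-site rate within 15%
    relative error and increase strictly with the rate.
    """
    p = SketchParams(k=21, s=5000)
    seeds = _subseeds(seed, n_replicates)
    means = {}
    for rate in rates:
        ds = []
        for s in seeds:
            anc = random_genome(SimParams(n_chrom=1, chrom_len=length, seed=s))["chr1"]
            der = evolve_sequence(anc, rate, seed=(s + 1) % _SEED_CAP)
            ds.append(
                mash_distance(
                    sketch_sequence(anc, "anc", p), sketch_sequence(der, "der", p)
                ).distance
            )
        means[rate] = float(np.mean(ds))
    rel_errors = {r: abs(means[r] - r) / r for r in rates}
    ordered = [means[r] for r in sorted(rates)]
    return {
        "mean_distance": means,
        "rel_error": rel_errors,
        "max_rel_error": max(rel_errors.values()),
        "monotone": all(a < b for a, b in zip(ordered, ordered[1:])),
        "n": n_replicates * len(rates),
    }


_PRESET = dict(n_chrom=10, chrom_len=200_000)
_RATES = dict(r_ref=0.05, r_B=0.02, r_C=0.08)


def _run_partition(ref, tetra, tau=0.05, s=5000):
    m = distance_matrix(tetra, ref, SketchParams(k=21, s=s))
    pairs = infer_homoeolog_pairs(m)
    from .partition import PartitionParams

    return assign_subgenomes(pairs, PartitionParams(tau=tau))


def _truth_accuracy(result, truth) -> float:
    """Fraction of chromosomes assigned to their true progenitor.

    The low-divergence label must coincide with the lower-rate progenitor
    (B at these settings); scored over both subgenomes.
    """
    correct = sum(
        1
        for chrom, label in result.assignments.items()
        if (label == result.params.label_low) == (truth.labels[chrom] == "B")
    )
    return correct / len(result.assignments)


def partition_recovery(seed: int, n_replicates: int = 20) -> dict:
    """Allotetraploid preset: every chromosome must recover its progenitor.

    10 chromosomes x 200 kb, reference branch rate 0.05, progenitor branches
    0.02 and 0.08; across replicates the assignment accuracy and the number
    of ambiguous pairs (tau = 0.05) are recorded.
    """
    accs, ambigs = [], []
    for s in _subseeds(seed, n_replicates):
        p = SimParams(seed=s, **_PRESET)
        ref, tetra, truth = make_allotetraploid(p, **_RATES)
        res = _run_partition(ref, tetra)
        accs.append(_truth_accuracy(res, truth))
        ambigs.append(res.n_ambiguous)
    return {
        "mean_accuracy": float(np.mean(accs)),
        "min_accuracy": float(np.min(accs)),
        "total_ambiguous": int(np.sum(ambigs)),
        "n": n_replicates,
    }


def negative_control(seed: int, n_replicates: int = 20) -> dict:
    """Equal progenitor rates: the method must declare itself indeterminate.

    With r_B = r_C there is no divergence signal; most pairs should be
    flagged ambiguous and the per-replicate verdict should be
    "indeterminate".
    """
    ambigs, verdicts = [], []
    for s in _subseeds(seed, n_replicates):
        p = SimParams(seed=s, **_PRESET)
        ref, tetra, _truth = make_allotetraploid(p, r_ref=0.05, r_B=0.05, r_C=0.05)
        res = _run_partition(ref, tetra)
        ambigs.append(res.n_ambiguous)
        verdicts.append(res.verdict)
    return {
        "median_ambiguous": float(np.median(ambigs)),
        "indeterminate_fraction": verdicts.count("indeterminate") / len(verdicts),
        "n": n_replicates,
    }


def masking_invariance(seed: int, n_replicates: int = 10) -> dict:
    """Hard-masking a 20% repeat fraction must not change any assignment."""
    agree = 0
    for s in _subseeds(seed, n_replicates):
        p = SimParams(seed=s, **_PRESET)
        ref, tetra, _truth = make_allotetraploid(p, **_RATES)
        tetra_r, bed_t = insert_repeats(tetra, repeat_fraction=0.2, seed=s)
        ref_r, bed_r = insert_repeats(ref, repeat_fraction=0.2, seed=s)
        unmasked = _run_partition(ref_r, tetra_r)
        masked = _run_partition(
            mask_intervals(ref_r, bed_r), mask_intervals(tetra_r, bed_t)
        )
        agree += unmasked.assignments == masked.assignments
    return {"agreeing_replicates": agree, "n": n_replicates}


def ploidy_recovery(
    seed: int,
    chrom_len: int = 500_000,
    coverage: float = 15.0,
    read_len: int = 100,
    error_rate: float = 0.005,
) -> dict:
    """AB vs AABB read sets: modal genotype and haploid-coverage recovery.

    The AB data set is a diploid with ~1 heterozygous site per kb. The AABB
    data set is an allotetraploid: two subgenomes diverged by ~2%, each
    present as two copies carrying low-rate residual heterozygosity (the
    mixture of fixed AABB heterozygosity with a minor AB/AAAB component
    that real allotetraploid read sets show). The ground-truth haploid
    coverage is at k-mer level: base coverage x (read_len-k+1)/read_len x
    (1-error_rate)^k.
    """
    k = 21
    c_true = coverage * (read_len - k + 1) / read_len * (1 - error_rate) ** k
    seeds = _subseeds(seed, 12)

    # -- AB diploid
    anc = random_genome(
        SimParams(n_chrom=1, chrom_len=chrom_len, seed=seeds[0])
    )["chr1"]
    hap2 = evolve_sequence(anc, 0.001, seed=seeds[1])
    reads = simulate_reads(
        [Haplotype("h1", anc), Haplotype("h2", hap2)],
        coverage_per_copy=coverage, read_len=read_len,
        error_rate=error_rate, seed=seeds[2],
    )
    ab, _pairs, _L = run_smudge_analysis((s for _n, s in reads), k=k)

    # -- AABB allotetraploid
    anc2 = random_genome(
        SimParams(n_chrom=1, chrom_len=chrom_len, seed=seeds[3])
    )["chr1"]
    sub1 = evolve_sequence(anc2, 0.01, seed=seeds[4])
    sub2 = evolve_sequence(anc2, 0.01, seed=seeds[5])
    haps = [
        Haplotype("s1a", sub1),
        Haplotype("s1b", evolve_sequence(sub1, 0.0005, seed=seeds[6])),
        Haplotype("s2a", sub2),
        Haplotype("s2b", evolve_sequence(sub2, 0.0005, seed=seeds[7])),
    ]
    reads = simulate_reads(
        haps, coverage_per_copy=coverage, read_len=read_len,
        error_rate=error_rate, seed=seeds[8],
    )
    aabb, _pairs, _L = run_smudge_analysis((s for _n, s in reads), k=k)

    return {
        "true_haploid_kmer_coverage": c_true,
        "ab_modal_genotype": ab.modal_genotype,
        "ab_coverage": ab.haploid_coverage,
        "ab_coverage_rel_error": abs(ab.haploid_coverage - c_true) / c_true,
        "aabb_modal_genotype": aabb.modal_genotype,
        "aabb_modal_proportion": aabb.proportions[aabb.modal_genotype],
        "aabb_coverage": aabb.haploid_coverage,
        "aabb_coverage_rel_error": abs(aabb.haploid_coverage - c_true) / c_true,
        "n": ab.n_pairs + aabb.n_pairs,
    }


def pairing_oracle(seed: int, n_trials: int = 20) -> dict:
    """Greedy pairing vs the exhaustive minimum-total-distance assignment.

    Random homoeolog-structured distance matrices (<= 8 reference
    chromosomes, two true homoeologs per reference well separated from the
    background); the greedy total distance must equal the optimum found by
    the Hungarian method on the row-duplicated matrix.
    """
    from scipy.optimize import linear_sum_assignment

    from .pairing import DistanceMatrix
    from .sketch import DistanceRecord

    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_trials):
        n = int(rng.integers(2, 9))
        arr = rng.uniform(0.2, 1.0, size=(n, 2 * n))
        for i in range(n):
            arr[i, 2 * i] = rng.uniform(0.01, 0.05)
            arr[i, 2 * i + 1] = rng.uniform(0.08, 0.15)
        refs = [f"r{i}" for i in range(n)]
        queries = [f"q{j}" for j in range(2 * n)]
        records = {
            (r, q): DistanceRecord(r, q, 0.0, 0, 1, arr[i, j])
            for i, r in enumerate(refs)
            for j, q in enumerate(queries)
        }
        m = DistanceMatrix(refs, queries, records, SketchParams())
        pairs = infer_homoeolog_pairs(m)
        greedy_total = sum(p.d_low + p.d_high for p in pairs)
        rows, cols = linear_sum_assignment(np.repeat(arr, 2, axis=0))
        optimal_total = float(np.repeat(arr, 2, axis=0)[rows, cols].sum())
        agree += bool(np.isclose(greedy_total, optimal_total))
    return {"agreeing_trials": agree, "n": n_trials}
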