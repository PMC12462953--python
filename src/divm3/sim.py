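"""Synthetic allopolyploid genomes, repeats and sequencing reads.

The generator realises the scenario the partitioning method is built for: an
ancestral diploid genome spawns two progenitor lineages that accumulate
substitutions (and optionally indels) at *different* per-branch rates, and a
third lineage that serves as the diploid reference; the two progenitors then
merge into an allotetraploid whose chromosomes carry known progenitor labels
(the truth table). Setting the two progenitor rates equal produces the
autopolyploid-like negative control in which no divergence signal exists.

Substitutions follow a Jukes–Cantor-style uniform exchange applied once per
branch (no multiple-hit bookkeeping; negligible below ~0.1 subs/site).
Indels are point events with geometric lengths, insertion and deletion
equiprobable. Everything is deterministic for a fixed seed.

Read simulation draws uniformly placed, error-prone reads from haplotype
copies with integer multiplicities, which is exactly the structure the
heterozygous k-mer-pair analysis interrogates: an AB diploid is two
haplotypes at multiplicity 1, an AABB allotetraploid two haplotypes at
multiplicity 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimParams:
    """Genome-simulation parameters.

    Rates are per-branch expectations: ``sub_rate`` substitutions/site,
    ``indel_rate`` indel events/site with geometric lengths of mean
    ``indel_mean_len``. ``gc`` is the stationary GC fraction (teleost
    genomes sit near 0.40).
    """

    n_chrom: int = 10
    chrom_len: int = 200_000
    gc: float = 0.40
    sub_rate: float = 0.05
    indel_rate: float = 0.0005
    indel_mean_len: float = 3.0
    repeat_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.gc <= 1:
            raise ValueError("gc must be in [0, 1]")
        for name in ("sub_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 0.5:
                raise ValueError(f"{name} must be in [0, 0.5], got {v}")
        if self.n_chrom < 1 or self.chrom_len < 1:
            raise ValueError("n_chrom and chrom_len must be positive")


@dataclass
class TruthTable:
    """Ground-truth progenitor labels of a simulated allotetraploid."""

    labels: dict[str, str]  # tetraploid chromosome id -> "B" | "C"
    ancestral: dict[str, str]  # tetraploid chromosome id -> ancestor chrom id

    def __len__(self) -> int:
        return len(self.labels)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASE_ARR[codes].tobytes().decode("ascii")


def _str_to_codes(seq: str) -> np.ndarray:
    lut = np.full(256, 255, np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    arr = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("simulated-genome operations require pure ACGT input")
    return arr


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _codes_to_str(rng.choice(4, size=length, p=p).astype(np.uint8))


def random_genome(p: SimParams) -> dict[str, str]:
    """n_chrom random chromosomes named chr1..chrN; deterministic per seed."""
    rng = np.random.default_rng(p.seed)
    return {
        f"chr{i + 1}": random_sequence(p.chrom_len, p.gc, rng)
        for i in range(p.n_chrom)
    }


def evolve_sequence(
    seq: str,
    sub_rate: float,
    indel_rate: float = 0.0,
    indel_mean_len: float = 3.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Derive a sequence by random substitutions and indels.

    Each site substitutes with probability ``sub_rate`` to a uniformly
    chosen different base. Indel events occur per site at ``indel_rate``;
    lengths are geometric with the given mean, insertion/deletion
    equiprobable, inserted bases uniform.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    codes = _str_to_codes(seq)
    n = codes.size
    if sub_rate > 0:
        hit = rng.random(n) < sub_rate
        shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
        codes = codes.copy()
        codes[hit] = (codes[hit] + shift) % 4
    if indel_rate > 0:
        n_events = rng.binomial(n, indel_rate)
        if n_events:
            pos = np.sort(rng.integers(0, n, size=n_events))
            lengths = rng.geometric(1.0 / indel_mean_len, size=n_events)
            is_ins = rng.random(n_events) < 0.5
            parts: list[np.ndarray] = []
            prev = 0
            for i in range(n_events):
                p_i = int(pos[i])
                L = int(lengths[i])
                if p_i < prev:
                    continue
                if is_ins[i]:
                    parts.append(codes[prev:p_i])
                    parts.append(rng.integers(0, 4, size=L).astype(np.uint8))
                    prev = p_i
                else:
                    parts.append(codes[prev:p_i])
                    prev = min(n, p_i + L)
            parts.append(codes[prev:])
            codes = np.concatenate(parts)
    return _codes_to_str(codes)


def evolve_genome(
    genome: dict[str, str],
    sub_rate: float,
    indel_rate: float,
    indel_mean_len: float,
    seed: int,
    rename: str | None = None,
) -> dict[str, str]:
    """Evolve every chromosome with one master seed; optional id prefix."""
    rng = np.random.default_rng(seed)
    out = {}
    for name, seq in genome.items():
        new_name = f"{rename}_{name}" if rename else name
        out[new_name] = evolve_sequence(
            seq, sub_rate, indel_rate, indel_mean_len, rng=rng
        )
    return out


def make_allotetraploid(
    p: SimParams, r_ref: float, r_B: float, r_C: float
) -> tuple[dict[str, str], dict[str, str], TruthTable]:
    """Simulate (reference genome, allotetraploid genome, truth table).

    The ancestor evolves independently into the reference lineage (rate
    ``r_ref``) and the two progenitors B and C (rates ``r_B``, ``r_C``); the
    tetraploid is the union of the B and C chromosome sets, relabelled
    ``B_chrN`` / ``C_chrN``. Equal r_B and r_C gives the no-signal negative
    control.
    """
    ancestor = random_genome(p)
    sub_seeds = np.random.default_rng(p.seed).integers(0, 2**31 - 1, size=3)
    kw = dict(indel_rate=p.indel_rate, indel_mean_len=p.indel_mean_len)
    ref = evolve_genome(ancestor, r_ref, seed=int(sub_seeds[0]), rename="ref", **kw)
    prog_b = evolve_genome(ancestor, r_B, seed=int(sub_seeds[1]), rename="B", **kw)
    prog_c = evolve_genome(ancestor, r_C, seed=int(sub_seeds[2]), rename="C", **kw)
    tetraploid = {**prog_b, **prog_c}
    labels = {name: name.split("_")[0] for name in tetraploid}
    ancestral = {name: name.split("_", 1)[1] for name in tetraploid}
    return ref, tetraploid, TruthTable(labels, ancestral)


def insert_repeats(
    genome: dict[str, str],
    repeat_len: int = 500,
    repeat_fraction: float | None = None,
    copies: int | None = None,
    seed: int = 0,
    per_copy_divergence: float = 0.02,
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Scatter mutated copies of one repeat monomer through a genome.

    Either ``copies`` (total insertions) or ``repeat_fraction`` (fraction of
    the *final* genome covered by repeat copies) must be given. Each copy
    carries independent per-base mutations at ``per_copy_divergence``.
    Returns the enlarged genome and a BED-style list of 0-based half-open
    insertion intervals in final coordinates.
    """
    rng = np.random.default_rng(seed)
    total_len = sum(len(s) for s in genome.values())
    if copies is None:
        if repeat_fraction is None:
            raise ValueError("give either copies or repeat_fraction")
        if not 0 <= repeat_fraction < 1:
            raise ValueError("repeat_fraction must be in [0, 1)")
        # inserted/(original+inserted) = f  =>  inserted = f/(1-f) * original
        copies = round(repeat_fraction / (1 - repeat_fraction) * total_len / repeat_len)
    if copies == 0:
        return dict(genome), []
    monomer = _str_to_codes(random_sequence(repeat_len, 0.5, rng))
    chrom_names = list(genome)
    weights = np.array([len(genome[c]) for c in chrom_names], dtype=float)
    chrom_of_copy = rng.choice(len(chrom_names), size=copies, p=weights / weights.sum())
    out: dict[str, str] = {}
    bed: list[tuple[str, int, int]] = []
    for ci, name in enumerate(chrom_names):
        codes = _str_to_codes(genome[name])
        k_copies = int(np.sum(chrom_of_copy == ci))
        if k_copies == 0:
            out[name] = genome[name]
            continue
        pos = np.sort(rng.integers(0, codes.size + 1, size=k_copies))
        parts: list[np.ndarray] = []
        prev = 0
        offset = 0
        for p_i in pos:
            copy = monomer.copy()
            hit = rng.random(repeat_len) < per_copy_divergence
            if hit.any():
                shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
                copy[hit] = (copy[hit] + shift) % 4
            parts.append(codes[prev : int(p_i)])
            parts.append(copy)
            start = int(p_i) + offset
            bed.append((name, start, start + repeat_len))
            offset += repeat_len
            prev = int(p_i)
        parts.append(codes[prev:])
        out[name] = _codes_to_str(np.concatenate(parts))
    return out, bed


def mask_intervals(
    genome: dict[str, str], bed: Iterable[tuple[str, int, int]]
) -> dict[str, str]:
    """Hard-mask (replace with N) the given 0-based half-open intervals."""
    arrays = {name: bytearray(seq.encode("ascii")) for name, seq in genome.items()}
    for chrom, start, end in bed:
        buf = arrays[chrom]
        buf[start:end] = b"N" * (end - start)
    return {name: buf.decode("ascii") for name, buf in arrays.items()}


@dataclass
class Haplotype:
    """One haplotype sequence present at an integer copy number."""

    name: str
    seq: str
    multiplicity: int = 1


def simulate_reads(
    haplotypes: Sequence[Haplotype],
    coverage_per_copy: float,
    read_len: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Uniform error-prone reads from haplotype copies; ``(name, seq)`` list.

    Each copy of each haplotype contributes ~``coverage_per_copy`` fold
    depth; reads are placed uniformly, strand chosen at random, and
    sequencing errors are independent substitutions at ``error_rate``.
    """
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    for hap in haplotypes:
        codes = _str_to_codes(hap.seq)
        n = codes.size
        if n < read_len:
            raise ValueError(f"haplotype {hap.name} shorter than read length")
        n_reads = int(round(hap.multiplicity * coverage_per_copy * n / read_len))
        starts = rng.integers(0, n - read_len + 1, size=n_reads)
        mat = codes[starts[:, None] + np.arange(read_len)[None, :]].copy()
        flip = rng.random(n_reads) < 0.5
        mat[flip] = (3 - mat[flip])[:, ::-1]
        if error_rate > 0:
            err = rng.random(mat.shape) < error_rate
            shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
            mat[err] = (mat[err] + shift) % 4
        ascii_mat = _BASE_ARR[mat]
        for i in range(n_reads):
            reads.append(
                (f"{hap.name}_r{i}", ascii_mat[i].tobytes().decode("ascii"))
            )
    return reads
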