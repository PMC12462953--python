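"""Bottom-s MinHash sketching of genome sequences and the Mash distance.

A *bottom-s sketch* of a sequence is the set of the s smallest 64-bit hash
values over its distinct canonical k-mers. Two sketches estimate the Jaccard
index j of the underlying k-mer sets from the s smallest hashes of their
union, and the Mash distance

    D = -(1/k) * ln( 2j / (1+j) )

converts j into an approximate per-base divergence under a Poisson model of
random substitutions. With a sketch size at least as large as the union of
the two k-mer sets the estimate is exact (``s=None`` keeps every hash, the
"exact" mode).

The hash is a seeded splitmix64 finalizer over the 2-bit packed canonical
k-mer; sketches built with different k or hash seeds are incomparable and
refuse to be compared. Hash values are not interchangeable with those of
other sketching tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from . import _kmers


@dataclass(frozen=True)
class SketchParams:
    """Sketching parameters.

    Parameters
    ----------
    k : odd k-mer length in [3, 31]; odd so no k-mer is its own reverse
        complement.
    s : sketch size (number of smallest hashes kept), or ``None`` to keep
        every hash (exact Jaccard).
    hash_seed : seed of the 64-bit hash; sketches are only comparable when
        it matches.
    fold_lowercase : treat soft-masked (lowercase) bases as their uppercase
        equivalents; when False lowercase windows are skipped like N runs.
    """

    k: int = 21
    s: int | None = 5000
    hash_seed: int = 42
    fold_lowercase: bool = True

    def __post_init__(self) -> None:
        if not (3 <= self.k <= _kmers.MAX_K) or self.k % 2 == 0:
            raise ValueError(
                f"k must be odd and in [3, {_kmers.MAX_K}], got {self.k}"
            )
        if self.s is not None and self.s < 1:
            raise ValueError(f"sketch size must be >= 1 or None, got {self.s}")

    def compatible(self, other: "SketchParams") -> bool:
        return (
            self.k == other.k
            and self.hash_seed == other.hash_seed
            and self.fold_lowercase == other.fold_lowercase
        )


@dataclass
class Sketch:
    """Bottom-s sketch of one sequence (chromosome or genome)."""

    name: str
    params: SketchParams
    hashes: np.ndarray  # sorted ascending, distinct uint64
    total_distinct: int  # distinct canonical k-mers observed

    def __post_init__(self) -> None:
        self.hashes = np.asarray(self.hashes, dtype=np.uint64)

    def __len__(self) -> int:
        return int(self.hashes.size)


@dataclass
class DistanceRecord:
    """Mash distance between one query and one reference sequence.

    ``jaccard_est = shared / denom`` where ``denom`` is the number of
    smallest union hashes examined; ``capped`` marks the j = 0 case where
    the distance is reported as the 1.0 ceiling.
    """

    ref_name: str
    query_name: str
    jaccard_est: float
    shared: int
    denom: int
    distance: float
    capped: bool = field(default=False)


def extract_canonical_kmers(seq: str, params: SketchParams) -> set[str]:
    """Distinct canonical k-mers of a sequence, as strings.

    Canonical means the lexicographic minimum of a k-mer and its reverse
    complement. Windows containing an ambiguity letter (N etc.) are skipped;
    a sequence shorter than k yields the empty set; characters outside the
    IUPAC alphabet raise ``ValueError`` naming the position.
    """
    if not seq:
        raise ValueError("empty sequence")
    codes = _kmers.encode(seq, params.fold_lowercase)
    canon = np.unique(_kmers.window_codes(codes, params.k))
    return {_kmers.code_to_kmer(c, params.k) for c in canon}


def _bottom(hashes: np.ndarray, s: int | None) -> np.ndarray:
    hashes = np.unique(hashes)  # sorted distinct
    if s is not None and hashes.size > s:
        hashes = hashes[:s]
    return hashes


def build_sketch(kmers: Iterable[str], name: str, params: SketchParams) -> Sketch:
    """Sketch an explicit k-mer collection (canonicalised defensively)."""
    codes = np.array(
        sorted({_kmers.kmer_to_code(_kmers.canonical(km)) for km in kmers}),
        dtype=np.uint64,
    )
    if codes.size == 0:
        raise ValueError(f"no valid k-mers for {name!r}")
    hashes = _bottom(_kmers.hash_codes(codes, params.hash_seed), params.s)
    return Sketch(name=name, params=params, hashes=hashes, total_distinct=codes.size)


def sketch_sequence(seq: str, name: str, params: SketchParams) -> Sketch:
    """Sketch a sequence directly (fast array path).

    Bit-identical to ``build_sketch(extract_canonical_kmers(seq, p), ...)``.
    """
    if not seq:
        raise ValueError(f"empty sequence for {name!r}")
    codes = _kmers.encode(seq, params.fold_lowercase)
    canon = np.unique(_kmers.window_codes(codes, params.k))
    if canon.size == 0:
        raise ValueError(
            f"no valid k-mers for {name!r} (all-N, fully masked, or shorter than k)"
        )
    hashes = _bottom(_kmers.hash_codes(canon, params.hash_seed), params.s)
    return Sketch(name=name, params=params, hashes=hashes, total_distinct=canon.size)


def mash_distance(ref: Sketch, query: Sketch) -> DistanceRecord:
    """Mash distance between two sketches built with compatible parameters.

    The estimator merges the two bottom sketches, keeps the ``denom``
    smallest distinct hashes of the union (``denom = min(s, |union|)``)
    and counts how many occur in both sketches. Symmetric in its arguments.
    """
    if not ref.params.compatible(query.params):
        raise ValueError(
            "incomparable sketches: k/hash_seed/case policy differ "
            f"({ref.params} vs {query.params})"
        )
    k = ref.params.k
    s_a, s_b = ref.params.s, query.params.s
    if s_a is None:
        s_eff = s_b
    elif s_b is None:
        s_eff = s_a
    else:
        s_eff = min(s_a, s_b)
    union = np.union1d(ref.hashes, query.hashes)
    denom = union.size if s_eff is None else min(s_eff, union.size)
    top = union[denom - 1]
    inter = np.intersect1d(ref.hashes, query.hashes, assume_unique=True)
    shared = int(np.count_nonzero(inter <= top))
    j = shared / denom
    if j <= 0.0:
        return DistanceRecord(ref.name, query.name, 0.0, 0, denom, 1.0, capped=True)
    if j >= 1.0:
        return DistanceRecord(ref.name, query.name, 1.0, shared, denom, 0.0)
    d = -np.log(2.0 * j / (1.0 + j)) / k
    return DistanceRecord(ref.name, query.name, j, shared, denom, float(d))


def mash_distance_from_jaccard(j: float, k: int) -> float:
    """The Mash transform alone: D = -(1/k) ln(2j/(1+j)), capped at 1 for j=0."""
    if j <= 0.0:
        return 1.0
    if j >= 1.0:
        return 0.0
    return float(-np.log(2.0 * j / (1.0 + j)) / k)


def jaccard_exact(seq_a: str, seq_b: str, params: SketchParams) -> float:
    """Exact Jaccard index of the two canonical k-mer sets (no hashing).

    Brute-force oracle: |A ∩ B| / |A ∪ B| over the full k-mer sets.
    """
    a = np.unique(
        _kmers.window_codes(_kmers.encode(seq_a, params.fold_lowercase), params.k)
    )
    b = np.unique(
        _kmers.window_codes(_kmers.encode(seq_b, params.fold_lowercase), params.k)
    )
    if a.size == 0 or b.size == 0:
        raise ValueError("a sequence yields no valid k-mers")
    inter = np.intersect1d(a, b, assume_unique=True).size
    union = a.size + b.size - inter
    return inter / union
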