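"""Vectorised 2-bit k-mer encoding, canonicalisation and hashing.

All k-mer work in the package funnels through this module so that the
string-level API (sets of canonical k-mer strings) and the fast array path
(uint64 codes straight from a chromosome or a read batch) are guaranteed to
agree bit-for-bit.

A k-mer of length k <= 31 is packed into a uint64 with A=0, C=1, G=2, T=3,
most-significant digit first; integer order on codes therefore equals
lexicographic order on the strings, so ``min(code, rc_code)`` is the
canonical k-mer.
"""

from __future__ import annotations

import numpy as np

MAX_K = 31

_BASES = "ACGT"

# 256-entry lookup tables: ACGT -> 0..3, ambiguity letters (IUPAC) -> 4
# (window skipped), everything else -> 255 (hard error).
_AMBIG = b"NRYSWKMBDHV"


def _make_table(fold_lowercase: bool) -> np.ndarray:
    t = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        t[b] = i
    for b in _AMBIG:
        t[b] = 4
    if fold_lowercase:
        for i, b in enumerate(b"acgt"):
            t[b] = i
        for b in _AMBIG.lower():
            t[b] = 4
    else:
        # lowercase is soft-masked sequence: valid letters, masked windows
        for b in b"acgt" + _AMBIG.lower():
            t[b] = 4
    return t


_TABLE_FOLD = _make_table(True)
_TABLE_NOFOLD = _make_table(False)


def encode(seq: str | bytes, fold_lowercase: bool = True) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (0-3 bases, 4 skip).

    Raises ``ValueError`` naming the first offending position for any
    character that is not an IUPAC nucleotide letter.
    """
    if isinstance(seq, str):
        raw = seq.encode("ascii", errors="replace")
    else:
        raw = bytes(seq)
    arr = np.frombuffer(raw, dtype=np.uint8)
    table = _TABLE_FOLD if fold_lowercase else _TABLE_NOFOLD
    codes = table[arr]
    bad = codes == 255
    if bad.any():
        pos = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"invalid nucleotide character {chr(raw[pos])!r} at position {pos}"
        )
    return codes


def window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical uint64 codes of every valid k-length window, in order.

    Windows containing a skip code (ambiguity letter, or soft-masked base
    when folding is off) are dropped. Returns an empty array when the
    sequence is shorter than k.
    """
    if not 3 <= k <= MAX_K:
        raise ValueError(f"k must be in [3, {MAX_K}], got {k}")
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    m = n - k + 1
    c = codes.astype(np.uint64)
    two = np.uint64(2)
    three = np.uint64(3)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    with np.errstate(over="ignore"):
        for j in range(k):
            col = c[j : j + m]
            fwd = (fwd << two) | (col & three)
            rev = rev | ((three - (col & three)) << np.uint64(2 * j))
    canon = np.minimum(fwd, rev)
    skip = codes > 3
    if skip.any():
        cs = np.concatenate(([0], np.cumsum(skip)))
        ok = (cs[k:] - cs[:-k]) == 0
        canon = canon[ok]
    return canon


def rc_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of packed k-mer codes (vectorised)."""
    codes = np.asarray(codes, dtype=np.uint64)
    three = np.uint64(3)
    out = np.zeros_like(codes)
    with np.errstate(over="ignore"):
        for j in range(k):
            digit = (codes >> np.uint64(2 * (k - 1 - j))) & three
            out = out | ((three - digit) << np.uint64(2 * j))
    return out


_MIX1 = 0x9E3779B97F4A7C15
_MIX2 = 0xBF58476D1CE4E5B9
_MIX3 = 0x94D049BB133111EB
_MASK64 = (1 << 64) - 1


def splitmix64(x: np.ndarray | int) -> np.ndarray | np.uint64:
    """splitmix64 finalizer: a fixed, well-mixed 64-bit hash."""
    arr = np.asarray(x, dtype=np.uint64)
    with np.errstate(over="ignore"):
        z = arr + np.uint64(_MIX1)
        z = (z ^ (z >> np.uint64(30))) * np.uint64(_MIX2)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(_MIX3)
        z = z ^ (z >> np.uint64(31))
    return z if z.shape else np.uint64(z)


def hash_codes(codes: np.ndarray, seed: int) -> np.ndarray:
    """Seeded 64-bit hash of packed k-mer codes."""
    codes = np.asarray(codes, dtype=np.uint64)
    seed_mix = splitmix64(np.uint64(seed & _MASK64))
    with np.errstate(over="ignore"):
        return splitmix64(codes ^ seed_mix)


def kmer_to_code(kmer: str) -> int:
    codes = encode(kmer, fold_lowercase=True)
    if (codes > 3).any():
        raise ValueError(f"k-mer {kmer!r} contains a non-ACGT base")
    val = 0
    for c in codes:
        val = (val << 2) | int(c)
    return val


def code_to_kmer(code: int, k: int) -> str:
    return "".join(_BASES[(int(code) >> (2 * (k - 1 - j))) & 3] for j in range(k))


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def canonical(kmer: str) -> str:
    rc = revcomp(kmer).upper()
    up = kmer.upper()
    return up if up <= rc else rc
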