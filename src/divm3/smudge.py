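"""Heterozygous k-mer-pair ploidy analysis.

A heterozygous site in sequencing reads shows up as two canonical k-mers
that differ at exactly one position. For each such pair, the *total*
coverage CovA + CovB and the minor-allele *ratio* CovB/(CovA + CovB) jointly
locate the pair near a genotype-specific centre:

    total ≈ m · c        (m = summed allele multiplicity, c = 1n coverage)
    ratio ≈ b / m        (b = copies of the minor allele, 1 <= b <= m/2)

An AB diploid site sits at (2c, 1/2); AABB fixed heterozygosity in an
allotetraploid at (4c, 1/2); AAB at (3c, 1/3), and so on. The workflow:
count canonical k-mers in reads, drop the low-depth error tail at the first
local minimum of the coverage histogram (or a user cutoff), enumerate
one-SNP pairs by per-position wildcard bucketing over both orientations,
estimate the haploid coverage c from the smudge-peak structure (comb fit
with a forbidden-mass veto and an Occam tie rule), and report the
genotype-class proportions with the modal class.

The ratio is defined minor/total in (0, 0.5] so each genotype centre is
unique.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import _kmers
from .io import iter_fastq_seqs

log = logging.getLogger(__name__)


@dataclass
class KmerCounts:
    """Canonical k-mer coverage counts from reads (codes sorted ascending)."""

    k: int
    kmers: np.ndarray  # uint64 packed canonical codes, sorted
    counts: np.ndarray  # int64, same length, all >= 1

    def __len__(self) -> int:
        return int(self.kmers.size)

    def filtered(self, min_count: int) -> "KmerCounts":
        keep = self.counts >= min_count
        return KmerCounts(self.k, self.kmers[keep], self.counts[keep])

    def to_dict(self) -> dict[str, int]:
        return {
            _kmers.code_to_kmer(km, self.k): int(c)
            for km, c in zip(self.kmers, self.counts)
        }

    @classmethod
    def from_dict(cls, counts: Mapping[str, int], k: int) -> "KmerCounts":
        codes = {}
        for km, c in counts.items():
            codes[_kmers.kmer_to_code(_kmers.canonical(km))] = (
                codes.get(_kmers.kmer_to_code(_kmers.canonical(km)), 0) + int(c)
            )
        keys = np.array(sorted(codes), dtype=np.uint64)
        vals = np.array([codes[int(x)] for x in keys], dtype=np.int64)
        return cls(k, keys, vals)


@dataclass
class HetKmerPair:
    """One-SNP canonical k-mer pair with read coverages (covB <= covA)."""

    kmer_major: str
    kmer_minor: str
    covA: int
    covB: int

    @property
    def total(self) -> int:
        return self.covA + self.covB

    @property
    def ratio(self) -> float:
        return self.covB / self.total


@dataclass
class SmudgeSummary:
    """Haploid coverage, genotype-class proportions and the modal class."""

    haploid_coverage: float
    proportions: dict[str, float]
    modal_genotype: str
    n_pairs: int


def count_kmers_from_reads(
    reads: str | PathLike | Iterable[str], k: int = 21, batch: int = 200_000
) -> KmerCounts:
    """Count canonical k-mers over reads (a FASTQ path or sequence iterable).

    Counting conventions are identical to the sketching module: windows
    containing a non-ACGT character are skipped.
    """
    if isinstance(reads, (str, PathLike)):
        seqs: Iterable[str] = iter_fastq_seqs(reads)
    else:
        seqs = reads
    chunks: list[np.ndarray] = []
    buf: list[np.ndarray] = []
    buffered = 0
    n_reads = 0
    for seq in seqs:
        n_reads += 1
        codes = _kmers.encode(seq, fold_lowercase=True)
        win = _kmers.window_codes(codes, k)
        if win.size:
            buf.append(win)
            buffered += win.size
        if buffered >= batch * 64:
            chunks.append(np.concatenate(buf))
            buf, buffered = [], 0
    if buf:
        chunks.append(np.concatenate(buf))
    if n_reads == 0:
        raise ValueError("no reads in input")
    if not chunks:
        raise ValueError("no read yielded a valid k-mer (reads shorter than k?)")
    allw = np.concatenate(chunks) if len(chunks) > 1 else chunks[0]
    kmers, counts = np.unique(allw, return_counts=True)
    return KmerCounts(k, kmers, counts.astype(np.int64))


def coverage_histogram(counts: KmerCounts, max_depth: int | None = None) -> np.ndarray:
    """h[d] = number of distinct k-mers with coverage d (index 0 unused)."""
    if max_depth is None:
        max_depth = int(counts.counts.max())
    return np.bincount(
        np.minimum(counts.counts, max_depth), minlength=max_depth + 1
    )


def depth_cutoff(counts: KmerCounts, user_cutoff: int | None = None) -> int:
    """Depth separating the sequencing-error tail from genomic k-mers.

    The first local minimum of the width-3 smoothed coverage histogram;
    k-mers with coverage below the returned depth are excluded downstream.
    A monotonically decreasing histogram has no minimum and raises, asking
    for an explicit cutoff.
    """
    if user_cutoff is not None:
        if user_cutoff < 1:
            raise ValueError("cutoff must be >= 1")
        return int(user_cutoff)
    if len(counts) == 0:
        raise ValueError("empty k-mer counts")
    h = coverage_histogram(counts).astype(float)
    if h.size < 4:
        raise ValueError(
            "coverage histogram too narrow to locate an error minimum; "
            "pass an explicit cutoff"
        )
    sm = h.copy()
    sm[1:-1] = (h[:-2] + h[1:-1] + h[2:]) / 3.0
    for d in range(2, sm.size - 1):
        if sm[d] <= sm[d - 1] and sm[d] < sm[d + 1]:
            return d
    raise ValueError(
        "coverage histogram is monotone (no local minimum); "
        "pass an explicit depth cutoff"
    )


def find_het_pairs(
    counts: KmerCounts, L: int, max_bucket: int = 16
) -> list[HetKmerPair]:
    """Enumerate one-SNP k-mer pairs among k-mers with coverage >= L.

    For every position i the k-mers are bucketed by their sequence with
    position i wildcarded, over *both* orientations, so canonical storage
    cannot hide a pair. Buckets larger than ``max_bucket`` (low-complexity
    or high-copy repeats) are skipped, duplicate discoveries are merged,
    and any k-mer participating in more than one distinct pair is dropped
    as an ambiguous paralog/repeat signal.
    """
    flt = counts.filtered(L)
    n = len(flt)
    if n == 0:
        return []
    k = flt.k
    fwd = flt.kmers.astype(np.uint64)
    rev = _kmers.rc_codes(fwd, k)
    idx = np.concatenate([np.arange(n), np.arange(n)])
    both = np.concatenate([fwd, rev])
    pair_set: set[tuple[int, int]] = set()
    for i in range(k):
        shift = np.uint64(2 * (k - 1 - i))
        mask = np.uint64(~(np.uint64(3) << shift) & ((1 << 64) - 1))
        keys = both & mask
        order = np.argsort(keys, kind="stable")
        ks = keys[order]
        run_starts = np.flatnonzero(np.concatenate(([True], ks[1:] != ks[:-1])))
        run_ends = np.concatenate((run_starts[1:], [ks.size]))
        big = run_ends - run_starts
        for a, b in zip(run_starts[big > 1], run_ends[big > 1]):
            if b - a > max_bucket:
                continue
            members = np.unique(idx[order[a:b]])
            for x in range(members.size):
                for y in range(x + 1, members.size):
                    pair_set.add((int(members[x]), int(members[y])))
    if not pair_set:
        return []
    participation = np.zeros(n, dtype=np.int64)
    for a, b in pair_set:
        participation[a] += 1
        participation[b] += 1
    cnt = flt.counts
    pairs: list[HetKmerPair] = []
    for a, b in sorted(pair_set):
        if participation[a] > 1 or participation[b] > 1:
            continue
        ca, cb = int(cnt[a]), int(cnt[b])
        km_a = _kmers.code_to_kmer(fwd[a], k)
        km_b = _kmers.code_to_kmer(fwd[b], k)
        if cb > ca or (cb == ca and km_b < km_a):
            (km_a, ca), (km_b, cb) = (km_b, cb), (km_a, ca)
        pairs.append(HetKmerPair(km_a, km_b, ca, cb))
    return pairs


def _genotype_centers(max_ploidy: int) -> list[tuple[int, int]]:
    """(m, b) grid: summed multiplicity m in 2..max_ploidy, minor copies
    b in 1..floor(m/2)."""
    return [
        (m, b) for m in range(2, max_ploidy + 1) for b in range(1, m // 2 + 1)
    ]


def genotype_label(m: int, b: int) -> str:
    return "A" * (m - b) + "B" * b


def _dominant_modes(
    totals: np.ndarray, ratios: np.ndarray
) -> list[tuple[float, float, float]]:
    """Dominant smudge modes as (total, ratio-mode, weight) triples.

    Total-axis modes are prominent local maxima (>= 5% prominence, minimum
    separation 30% of the median total) of a lightly smoothed integer
    histogram, refined by parabolic interpolation; each mode's ratio is the
    mode of its members' ratio histogram. Minority smudges that do not rise
    to a histogram peak are deliberately ignored here — they are accounted
    for by the forbidden-mass test during coverage estimation.
    """
    from scipy.signal import find_peaks

    hist = np.bincount(np.round(totals).astype(int)).astype(float)
    med = float(np.median(totals))
    width = max(1, int(round(0.25 * np.sqrt(med))))
    kernel = np.ones(2 * width + 1) / (2 * width + 1)
    padded = np.concatenate((np.zeros(width + 1), hist, np.zeros(width + 1)))
    sm = np.convolve(padded, kernel, mode="same")
    locs, _ = find_peaks(sm, prominence=0.05 * sm.max(),
                         distance=max(2, int(0.3 * med)))
    locs = locs - (width + 1)
    locs = locs[(locs >= 0) & (locs < hist.size)]
    if locs.size == 0:  # all mass in one bin
        locs = np.array([int(np.argmax(hist))])
    peak_t = []
    for loc in locs:
        i = loc + width + 1
        denom = sm[i - 1] - 2 * sm[i] + sm[i + 1]
        frac = 0.5 * (sm[i - 1] - sm[i + 1]) / denom if denom < 0 else 0.0
        peak_t.append(loc + float(np.clip(frac, -0.5, 0.5)))
    # recentre each peak by an iterative median (junk tails bias the raw
    # histogram peak downward)
    refined = []
    for t in peak_t:
        t_cur = float(t)
        for _ in range(3):
            window = totals[np.abs(totals - t_cur) <= 2.5 * np.sqrt(1.2 * t_cur)]
            if window.size == 0:
                break
            t_cur = float(np.median(window))
        refined.append(t_cur)
    peak_t = np.array(refined)
    assign = np.argmin(np.abs(totals[:, None] - peak_t[None, :]), axis=1)
    out: list[tuple[float, float, float]] = []
    for i, t in enumerate(peak_t):
        members = ratios[assign == i]
        if members.size == 0:
            continue
        out.append((float(t), _ratio_mode(members), members.size / totals.size))
    return out


def _ratio_mode(r: np.ndarray) -> float:
    """Mode of a ratio sample in (0, 0.5] (sharper than the mean/median
    under the fold at 0.5)."""
    if r.size < 30:
        return float(np.median(r))
    hist, edges = np.histogram(r, bins=25, range=(0.0, 0.5))
    sm = np.convolve(hist.astype(float), np.ones(3) / 3, mode="same")
    i = int(np.argmax(sm))
    lo = sm[i - 1] if i > 0 else 0.0
    hi = sm[i + 1] if i < sm.size - 1 else 0.0
    denom = lo - 2 * sm[i] + hi
    frac = 0.5 * (lo - hi) / denom if denom < 0 else 0.0
    return float(edges[i] + (0.5 + np.clip(frac, -0.5, 0.5)) * (edges[1] - edges[0]))


def estimate_haploid_coverage(
    pairs: list[HetKmerPair],
    L: int | None = None,
    max_ploidy: int = 8,
    tie_margin: float = 0.05,
    forbidden_frac: float = 0.02,
) -> float:
    """Estimate the 1n (haploid) k-mer coverage c from the smudge structure.

    Genotype centres lie at (total = m\u00b7c, ratio = b/m); a candidate c is
    scored by how well the dominant smudge modes sit on that comb, in scaled
    residuals ((T - m c)/c and (R - b/m)\u00b7m with m = round(T/c) clipped to
    [2, max_ploidy]). Two safeguards make the estimate identifiable:

    * forbidden-mass test — a candidate is rejected when more than
      ``forbidden_frac`` of all pairs lie further from every allowed centre
      than 3 standard deviations (dispersion estimated from the heaviest
      smudge), so minority smudges (e.g. an AB cluster at 2c under an AABB
      genome) veto any c that cannot place them;
    * Occam tie rule — among candidates fitting within ``tie_margin`` of
      the best, the LARGEST c (the smallest-multiplicity reading) wins. A
      lone smudge at total 2c is therefore read as AB, the only reading
      under which a diploid data set returns its true coverage.

    Candidates are T/m for every dominant mode T and m in 2..max_ploidy,
    bounded below by L (defaulting to the smallest observed minor
    coverage). The winner is polished by weighted least squares.
    """
    if len(pairs) < 5:
        raise ValueError(f"insufficient pairs ({len(pairs)} < 5)")
    totals = np.array([p.total for p in pairs], dtype=float)
    ratios = np.array([p.ratio for p in pairs], dtype=float)
    modes = _dominant_modes(totals, ratios)
    lo = float(L) if L is not None else float(min(p.covB for p in pairs))
    hi = max(t for t, _r, _w in modes)
    # dispersion index of the heaviest smudge (variance-to-mean of totals);
    # the window must span several sigma or the MAD underestimates badly
    t0, _r0, _w0 = max(modes, key=lambda m: m[2])
    near = totals[np.abs(totals - t0) <= 2.5 * np.sqrt(1.2 * t0)]
    sigma = 1.4826 * float(np.median(np.abs(near - np.median(near)))) if near.size else 0.0
    phi = sigma**2 / t0 if t0 > 0 else 0.0

    def forbidden_mass(c: float) -> float:
        """Fraction of pairs further than ~3 sigma from every allowed centre.

        A pair violates on the total axis (beyond the dispersion of its
        nearest multiple of c) or on the ratio axis (beyond binomial noise
        around the nearest allowed b/m for its multiplicity); either is
        evidence the candidate c cannot generate this pair.
        """
        # 4 sigma on the total axis: the empirical distribution has a narrow
        # core with heavier error-driven tails, so 3 sigma of the robust
        # spread flags genuine pairs
        m = np.clip(np.round(totals / c), 2, max_ploidy)
        slack = np.maximum(4.0 * np.sqrt(phi * m * c), 0.05 * m * c)
        t_viol = np.abs(totals - m * c) > slack
        b = np.clip(np.round(ratios * m), 1, np.maximum(1, m // 2))
        centre = b / m
        sig_r = np.maximum(np.sqrt(centre * (1 - centre) / totals), 0.05 / 3)
        r_viol = np.abs(ratios - centre) > 3.0 * sig_r
        return float(np.mean(t_viol | r_viol))

    def mode_fit(c: float) -> float:
        j = 0.0
        wsum = 0.0
        for t, r, w in modes:
            m = int(np.clip(round(t / c), 2, max_ploidy))
            b = int(np.clip(round(r * m), 1, max(1, m // 2)))
            j += w * (((t - m * c) / c) ** 2 + ((r - b / m) * m) ** 2)
            wsum += w
        return j / wsum

    cand = sorted(
        {
            float(t / m)
            for t, _r, _w in modes
            for m in range(2, max_ploidy + 1)
            if lo <= t / m <= hi
        }
    )
    if not cand:
        cand = [max(lo, hi / 2)]
    obj = np.array(
        [
            mode_fit(c) if forbidden_mass(c) <= forbidden_frac else np.inf
            for c in cand
        ]
    )
    if not np.isfinite(obj).any():  # no candidate explains the data; fall back
        obj = np.array([mode_fit(c) for c in cand])
    best = float(obj.min())
    ties = np.array(cand)[obj <= best + tie_margin]
    c0 = float(ties.max())
    # weighted least-squares polish with multiplicities fixed at c0
    ts = np.array([t for t, _r, _w in modes])
    ws = np.array([w for _t, _r, w in modes])
    ms = np.clip(np.round(ts / c0), 2, max_ploidy)
    c_ref = float(np.sum(ws * ms * ts) / np.sum(ws * ms**2))
    if forbidden_mass(c_ref) <= forbidden_frac and mode_fit(c_ref) <= mode_fit(c0) + 1e-12:
        return c_ref
    return c0


def classify_genotypes(
    pairs: list[HetKmerPair], c: float, max_ploidy: int = 8
) -> SmudgeSummary:
    """Assign every pair to its nearest genotype centre and summarise.

    Centres are (total = m·c, ratio = b/m); the metric scales the coverage
    residual by c and the ratio residual by m so the two axes are
    comparable across ploidy levels.
    """
    if c <= 0:
        raise ValueError("haploid coverage must be positive")
    if not pairs:
        raise ValueError("no heterozygous k-mer pairs to classify")
    totals = np.array([p.total for p in pairs], dtype=float)
    ratios = np.array([p.ratio for p in pairs], dtype=float)
    centers = _genotype_centers(max_ploidy)
    # total-axis dispersion index around the nearest multiple of c
    m_hat = np.clip(np.round(totals / c), 2, max_ploidy)
    z = (totals - m_hat * c) / np.sqrt(m_hat * c)
    phi = max((1.4826 * float(np.median(np.abs(z - np.median(z))))) ** 2, 0.3)
    # mixture-aware assignment: a genotype class is a 2-D Gaussian at
    # (m c, b/m) with variances (phi m c, b/m(1-b/m)/total); a few EM
    # rounds let the class weights pull tail pairs back into the dominant
    # smudge instead of spilling them into neighbouring multiplicities
    loglik = np.stack(
        [
            -0.5 * (totals - m * c) ** 2 / (phi * m * c)
            - 0.5 * np.log(phi * m * c)
            - 0.5 * (ratios - b / m) ** 2
            / np.maximum((b / m) * (1 - b / m) / totals, 1e-4)
            - 0.5 * np.log(np.maximum((b / m) * (1 - b / m) / totals, 1e-4))
            for m, b in centers
        ]
    )
    nearest = np.argmax(loglik, axis=0)
    pi = np.bincount(nearest, minlength=len(centers)).astype(float) + 0.5
    pi /= pi.sum()
    for _ in range(5):
        logpost = loglik + np.log(pi)[:, None]
        logpost -= logpost.max(axis=0, keepdims=True)
        post = np.exp(logpost)
        post /= post.sum(axis=0, keepdims=True)
        pi = post.mean(axis=1) + 1e-12
        pi /= pi.sum()
    nearest = np.argmax(loglik + np.log(pi)[:, None], axis=0)
    labels = [genotype_label(*centers[i]) for i in nearest]
    frac: dict[str, float] = {}
    for lab in labels:
        frac[lab] = frac.get(lab, 0.0) + 1.0
    n = len(labels)
    proportions = {lab: v / n for lab, v in sorted(frac.items())}
    modal = max(proportions, key=lambda lab: proportions[lab])
    return SmudgeSummary(
        haploid_coverage=float(c),
        proportions=proportions,
        modal_genotype=modal,
        n_pairs=n,
    )


def pairs_to_dataframe(pairs: list[HetKmerPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "kmer_major": [p.kmer_major for p in pairs],
            "kmer_minor": [p.kmer_minor for p in pairs],
            "covA": [p.covA for p in pairs],
            "covB": [p.covB for p in pairs],
            "total": [p.total for p in pairs],
            "ratio": [p.ratio for p in pairs],
        }
    )


def smudge_histogram2d(
    pairs: list[HetKmerPair], n_total_bins: int = 40, n_ratio_bins: int = 25
) -> pd.DataFrame:
    """2-D (total, ratio) histogram as a long-format table for plotting."""
    totals = np.array([p.total for p in pairs], dtype=float)
    ratios = np.array([p.ratio for p in pairs], dtype=float)
    h, tedges, redges = np.histogram2d(
        totals,
        ratios,
        bins=[n_total_bins, n_ratio_bins],
        range=[[0, totals.max() * 1.02], [0.0, 0.5]],
    )
    rows = []
    for i in range(n_total_bins):
        for j in range(n_ratio_bins):
            if h[i, j] > 0:
                rows.append(
                    {
                        "total_lo": tedges[i],
                        "total_hi": tedges[i + 1],
                        "ratio_lo": redges[j],
                        "ratio_hi": redges[j + 1],
                        "count": int(h[i, j]),
                    }
                )
    return pd.DataFrame(rows)


def run_smudge_analysis(
    reads: str | PathLike | Iterable[str],
    k: int = 21,
    cutoff: int | None = None,
    max_ploidy: int = 8,
) -> tuple[SmudgeSummary, list[HetKmerPair], int]:
    """Full pipeline: count → cutoff → pairs → coverage → classification.

    Returns (summary, pairs, depth cutoff used).
    """
    counts = count_kmers_from_reads(reads, k=k)
    L = depth_cutoff(counts, cutoff)
    log.info("depth cutoff L=%d over %d distinct k-mers", L, len(counts))
    pairs = find_het_pairs(counts, L)
    log.info("found %d heterozygous k-mer pairs", len(pairs))
    c = estimate_haploid_coverage(pairs, L=L, max_ploidy=max_ploidy)
    summary = classify_genotypes(pairs, c, max_ploidy=max_ploidy)
    return summary, pairs, L
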