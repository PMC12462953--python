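"""Polyploid-vs-reference distance matrices and homoeologous chromosome pairing.

Each polyploid chromosome is compared against every chromosome of a related
diploid reference with the Mash distance; a reference chromosome's two (for a
tetraploid) nearest, mutually exclusive polyploid chromosomes are taken to be
its homoeologs. Homology may instead be fixed from a user-supplied table
(e.g. derived from collinearity analysis), in which case only the distances
are filled in here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from os import PathLike
from typing import Mapping

import pandas as pd

from .io import as_genome
from .sketch import DistanceRecord, Sketch, SketchParams, mash_distance, sketch_sequence

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Complete all-vs-all Mash distances, reference x polyploid."""

    ref_names: list[str]
    query_names: list[str]
    records: dict[tuple[str, str], DistanceRecord]
    params: SketchParams

    def distance(self, ref: str, query: str) -> float:
        return self.records[(ref, query)].distance

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "ref": r.ref_name,
                "query": r.query_name,
                "shared": r.shared,
                "denom": r.denom,
                "jaccard": r.jaccard_est,
                "distance": r.distance,
            }
            for r in self.records.values()
        ]
        return pd.DataFrame(rows).sort_values(["ref", "query"]).reset_index(drop=True)


@dataclass
class HomoeologPair:
    """A reference chromosome with its two polyploid homoeologs.

    ``member_low`` is the homoeolog at the smaller Mash distance to the
    reference chromosome (d_low <= d_high always).
    """

    ref_chrom: str
    member_low: str
    member_high: str
    d_low: float
    d_high: float

    def __post_init__(self) -> None:
        if self.member_low == self.member_high:
            raise ValueError(f"pair on {self.ref_chrom} repeats {self.member_low}")
        if self.d_low > self.d_high:
            self.member_low, self.member_high = self.member_high, self.member_low
            self.d_low, self.d_high = self.d_high, self.d_low


def sketch_genome(
    genome: str | PathLike | Mapping[str, str], params: SketchParams
) -> list[Sketch]:
    """Sketch every chromosome; chromosomes with no valid k-mer are dropped
    with a warning (all-N or shorter than k)."""
    sketches = []
    for name, seq in as_genome(genome).items():
        try:
            sketches.append(sketch_sequence(seq, name, params))
        except ValueError as exc:
            log.warning("skipping chromosome %s: %s", name, exc)
    if not sketches:
        raise ValueError("no chromosome yielded a valid sketch")
    return sketches


def distance_matrix(
    poly_genome: str | PathLike | Mapping[str, str],
    ref_genome: str | PathLike | Mapping[str, str],
    params: SketchParams | None = None,
) -> DistanceMatrix:
    """All reference-chromosome x polyploid-chromosome Mash distances."""
    params = params or SketchParams()
    ref_sketches = sketch_genome(ref_genome, params)
    poly_sketches = sketch_genome(poly_genome, params)
    records = {
        (r.name, q.name): mash_distance(r, q)
        for r in ref_sketches
        for q in poly_sketches
    }
    return DistanceMatrix(
        ref_names=[s.name for s in ref_sketches],
        query_names=[s.name for s in poly_sketches],
        records=records,
        params=params,
    )


def infer_homoeolog_pairs(
    m: DistanceMatrix, copies_per_ref: int = 2
) -> list[HomoeologPair]:
    """Greedy global assignment of polyploid chromosomes to reference chromosomes.

    All (ref, query) records are visited in ascending distance (ties broken
    lexicographically on names, making the result independent of input
    order); a query binds to a ref unless the query is already bound or the
    ref already holds ``copies_per_ref`` members. Reference chromosomes left
    with fewer members, and unbound polyploid chromosomes, are reported with
    a warning — a signal of fused or rearranged chromosomes — and omitted
    from the returned pairs.
    """
    if len(m.query_names) != copies_per_ref * len(m.ref_names):
        log.warning(
            "chromosome counts (%d ref, %d polyploid) do not match "
            "copies_per_ref=%d; returning a partial pairing",
            len(m.ref_names),
            len(m.query_names),
            copies_per_ref,
        )
    order = sorted(
        m.records.values(), key=lambda r: (r.distance, r.ref_name, r.query_name)
    )
    members: dict[str, list[tuple[str, float]]] = {r: [] for r in m.ref_names}
    bound: set[str] = set()
    for rec in order:
        if rec.query_name in bound:
            continue
        got = members[rec.ref_name]
        if len(got) >= copies_per_ref:
            continue
        got.append((rec.query_name, rec.distance))
        bound.add(rec.query_name)
    pairs = []
    for ref in m.ref_names:
        got = members[ref]
        if len(got) == 2:
            (q1, d1), (q2, d2) = got
            pairs.append(HomoeologPair(ref, q1, q2, d1, d2))
        elif copies_per_ref != 2 and len(got) == copies_per_ref:
            # higher-ploidy groups are exposed through the matrix itself;
            # HomoeologPair is inherently pairwise
            log.warning("ref %s has %d members; only pairs are emitted", ref, len(got))
        else:
            log.warning(
                "ref %s bound %d of %d members: %s", ref, len(got), copies_per_ref, got
            )
    leftover = set(m.query_names) - bound
    if leftover:
        log.warning("unbound polyploid chromosomes: %s", sorted(leftover))
    return pairs


def load_pairs_file(
    path: str | PathLike, matrix: DistanceMatrix | None = None
) -> list[HomoeologPair]:
    """Read a homoeolog table (TSV: ref_chrom, poly_chrom_1, poly_chrom_2).

    When a distance matrix is supplied the pair distances are filled from it
    and the known chromosome ids are validated; the member order in the file
    carries no meaning — labels downstream always follow distance.
    """
    pairs: list[HomoeologPair] = []
    seen_poly: set[str] = set()
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[:3] == ["ref_chrom", "poly_chrom_1", "poly_chrom_2"]:
                continue  # header
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            ref, p1, p2 = fields[:3]
            for p in (p1, p2):
                if p in seen_poly:
                    raise ValueError(
                        f"{path}:{lineno}: polyploid chromosome {p!r} listed twice"
                    )
                seen_poly.add(p)
            if matrix is not None:
                for chrom, pool, kind in (
                    (ref, matrix.ref_names, "reference"),
                    (p1, matrix.query_names, "polyploid"),
                    (p2, matrix.query_names, "polyploid"),
                ):
                    if chrom not in pool:
                        raise ValueError(
                            f"{path}:{lineno}: unknown {kind} chromosome {chrom!r}"
                        )
                d1 = matrix.distance(ref, p1)
                d2 = matrix.distance(ref, p2)
            else:
                d1 = d2 = float("nan")
            pairs.append(HomoeologPair(ref, p1, p2, d1, d2))
    return pairs
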