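"""Subgenome assignment from differential Mash divergence (the decision rule).

The premise: the two progenitors of an allotetraploid diverged from a common
ancestor at different effective rates, so against any related diploid
reference one subgenome consistently shows larger Mash distances than the
other. Each homoeolog pair is therefore split independently — the member
closer to the reference goes to the low-divergence subgenome, the farther
one to the high-divergence subgenome — and the per-pair *relative gap*

    g = (d_high - d_low) / mean(d_low, d_high)

quantifies how much signal supported that call. Pairs with g below a
threshold ``tau`` are flagged ambiguous; when most pairs are ambiguous the
genome as a whole is declared indeterminate (the autopolyploid / equal-rate
failure mode, where the method has no signal to work with).

Assignment says nothing about which subgenome is maternal vs paternal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .pairing import HomoeologPair


@dataclass(frozen=True)
class PartitionParams:
    """tau: relative-gap ambiguity threshold (dimensionless, >= 0)."""

    tau: float = 0.05
    label_low: str = "subA"
    label_high: str = "subB"

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        if self.label_low == self.label_high:
            raise ValueError("subgenome labels must differ")


@dataclass
class PairCall:
    """Per-pair outcome of the decision rule."""

    ref_chrom: str
    member_low: str
    member_high: str
    d_low: float
    d_high: float
    abs_gap: float
    rel_gap: float
    ambiguous: bool


@dataclass
class PartitionResult:
    assignments: dict[str, str]  # chromosome id -> subgenome label
    calls: list[PairCall]
    params: PartitionParams
    ref_name: str | None = field(default=None)

    @property
    def n_ambiguous(self) -> int:
        return sum(c.ambiguous for c in self.calls)

    @property
    def verdict(self) -> str:
        """"partitioned" unless more than half the pairs are ambiguous."""
        if self.n_ambiguous > len(self.calls) / 2:
            return "indeterminate"
        return "partitioned"

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            for member, dist, label in (
                (c.member_low, c.d_low, self.params.label_low),
                (c.member_high, c.d_high, self.params.label_high),
            ):
                rows.append(
                    {
                        "chromosome": member,
                        "subgenome": label,
                        "ref_chrom": c.ref_chrom,
                        "distance": dist,
                        "rel_gap": c.rel_gap,
                        "ambiguous": c.ambiguous,
                    }
                )
        return pd.DataFrame(rows)


def assign_subgenomes(
    pairs: Sequence[HomoeologPair],
    params: PartitionParams | None = None,
    ref_name: str | None = None,
) -> PartitionResult:
    """Apply the decision rule independently to every homoeolog pair.

    The lower-distance member receives ``label_low``. Exact ties are broken
    lexicographically on chromosome name (and flagged ambiguous, as is any
    pair whose relative gap falls below tau).
    """
    if not pairs:
        raise ValueError("no homoeolog pairs to partition")
    params = params or PartitionParams()
    assignments: dict[str, str] = {}
    calls: list[PairCall] = []
    for p in pairs:
        lo_member, hi_member = p.member_low, p.member_high
        lo_d, hi_d = p.d_low, p.d_high
        if lo_d == hi_d and lo_member > hi_member:
            lo_member, hi_member = hi_member, lo_member
        abs_gap = hi_d - lo_d
        mean = 0.5 * (lo_d + hi_d)
        rel_gap = abs_gap / mean if mean > 0 else 0.0
        calls.append(
            PairCall(
                ref_chrom=p.ref_chrom,
                member_low=lo_member,
                member_high=hi_member,
                d_low=lo_d,
                d_high=hi_d,
                abs_gap=abs_gap,
                rel_gap=rel_gap,
                ambiguous=rel_gap < params.tau or lo_d == hi_d,
            )
        )
        assignments[lo_member] = params.label_low
        assignments[hi_member] = params.label_high
    return PartitionResult(assignments, calls, params, ref_name)


def summarize_partition(result: PartitionResult) -> tuple[pd.DataFrame, str]:
    """Per-subgenome summary table and the overall verdict.

    Columns: chromosome count, mean/min/max distance to the reference and
    the ambiguous-pair count; the verdict is "indeterminate" when more than
    half the pairs are ambiguous.
    """
    rows = []
    for label, dists in (
        (result.params.label_low, [c.d_low for c in result.calls]),
        (result.params.label_high, [c.d_high for c in result.calls]),
    ):
        rows.append(
            {
                "subgenome": label,
                "n_chromosomes": len(dists),
                "mean_distance": sum(dists) / len(dists),
                "min_distance": min(dists),
                "max_distance": max(dists),
                "n_ambiguous_pairs": result.n_ambiguous,
            }
        )
    return pd.DataFrame(rows), result.verdict


def consensus_partition(results: Sequence[PartitionResult]) -> pd.DataFrame:
    """Majority-vote consensus over partitions against multiple references.

    Testing several reference species sharpens ambiguous cases; each
    chromosome's consensus label is the majority label across references,
    with the agreement fraction reported (0.5 means a split vote).
    """
    if not results:
        raise ValueError("no partitions to combine")
    chroms = sorted(results[0].assignments)
    rows = []
    for chrom in chroms:
        votes = Counter(
            r.assignments[chrom] for r in results if chrom in r.assignments
        )
        label, n = votes.most_common(1)[0]
        total = sum(votes.values())
        rows.append(
            {
                "chromosome": chrom,
                "consensus_subgenome": label,
                "agreement": n / total,
                "n_references": total,
            }
        )
    return pd.DataFrame(rows)
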