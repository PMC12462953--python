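"""Optional matplotlib figures; never load-bearing for any result."""

from __future__ import annotations

from os import PathLike

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .partition import PartitionResult


def plot_partition_bars(result: PartitionResult, path: str | PathLike) -> None:
    """Per-reference-chromosome paired bars of homoeolog Mash distances.

    Blue/red encode the low/high-divergence subgenome of each pair;
    hatched bars mark ambiguous pairs.
    """
    calls = sorted(result.calls, key=lambda c: c.ref_chrom)
    x = range(len(calls))
    width = 0.38
    fig, ax = plt.subplots(figsize=(max(6, len(calls) * 0.7), 4))
    for offs, which, color in ((-width / 2, "low", "#3b6fb6"), (width / 2, "high", "#c0392b")):
        heights = [c.d_low if which == "low" else c.d_high for c in calls]
        hatches = ["//" if c.ambiguous else "" for c in calls]
        bars = ax.bar([xi + offs for xi in x], heights, width, color=color)
        for bar, hatch in zip(bars, hatches):
            bar.set_hatch(hatch)
    ax.set_xticks(list(x))
    ax.set_xticklabels([c.ref_chrom for c in calls], rotation=60, ha="right")
    ax.set_ylabel("Mash distance to reference")
    ax.set_xlabel("reference chromosome")
    label_lo, label_hi = result.params.label_low, result.params.label_high
    ax.legend([label_lo, label_hi], frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
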