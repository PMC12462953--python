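"""FASTA/FASTQ input (plain or gzipped) and sketch serialization.

Genomes are handled as plain ``{name: sequence}`` mappings — chromosome-level
assemblies of the sizes this tool targets fit comfortably in memory, and a
mapping keeps the pairing and partitioning code independent of file layout.

Sketches are serialized to a small documented JSON container rather than any
binary sketch format, so runs are auditable with standard tools.
"""

from __future__ import annotations

import gzip
import json
from os import PathLike
from pathlib import Path
from typing import IO, Iterator, Mapping

import numpy as np
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .sketch import Sketch, SketchParams

SKETCH_FORMAT_VERSION = 1


def _open_text(path: str | PathLike) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | PathLike) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA file into ``{record id: sequence}``."""
    with _open_text(path) as fh:
        genome = {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
    if not genome:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def write_fasta(genome: Mapping[str, str], path: str | PathLike, width: int = 80) -> None:
    with open(path, "wt") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def as_genome(source: str | PathLike | Mapping[str, str]) -> dict[str, str]:
    """Accept either a FASTA path or an in-memory genome mapping."""
    if isinstance(source, Mapping):
        return dict(source)
    return read_fasta(source)


def iter_fastq_seqs(path: str | PathLike) -> Iterator[str]:
    """Yield read sequences from a (possibly gzipped) FASTQ file."""
    with _open_text(path) as fh:
        for _title, seq, _qual in FastqGeneralIterator(fh):
            yield seq


def write_fastq(reads: Iterator[tuple[str, str]] | list[tuple[str, str]],
                path: str | PathLike) -> None:
    """Write ``(name, sequence)`` reads with uniform placeholder qualities."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def save_sketches(sketches: list[Sketch], path: str | PathLike) -> None:
    payload = {
        "format": "divm3-sketch",
        "version": SKETCH_FORMAT_VERSION,
        "hash": "splitmix64(code ^ splitmix64(seed)) over 2-bit canonical k-mer codes",
        "sketches": [
            {
                "name": sk.name,
                "k": sk.params.k,
                "s": sk.params.s,
                "hash_seed": sk.params.hash_seed,
                "fold_lowercase": sk.params.fold_lowercase,
                "total_distinct": sk.total_distinct,
                "hashes": [int(h) for h in sk.hashes],
            }
            for sk in sketches
        ],
    }
    with open(path, "wt") as fh:
        json.dump(payload, fh)
        fh.write("\n")


def load_sketches(path: str | PathLike) -> list[Sketch]:
    with open(path, "rt") as fh:
        payload = json.load(fh)
    if payload.get("format") != "divm3-sketch":
        raise ValueError(f"{path} is not a divm3 sketch file")
    out = []
    for entry in payload["sketches"]:
        params = SketchParams(
            k=entry["k"],
            s=entry["s"],
            hash_seed=entry["hash_seed"],
            fold_lowercase=entry["fold_lowercase"],
        )
        out.append(
            Sketch(
                name=entry["name"],
                params=params,
                hashes=np.array(entry["hashes"], dtype=np.uint64),
                total_distinct=entry["total_distinct"],
            )
        )
    return out


def write_bed(intervals: list[tuple[str, int, int]], path: str | PathLike) -> None:
    """Write 0-based half-open intervals as BED3."""
    with open(path, "wt") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed(path: str | PathLike) -> list[tuple[str, int, int]]:
    out = []
    with open(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append((chrom, int(start), int(end)))
    return out
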