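"""File formats and the in-memory read container.

FASTQ parsing goes through Biopython's ``FastqGeneralIterator``; FASTA
through ``Bio.SeqIO``.  Qualities are Phred+33 throughout and are held as
``uint8`` arrays.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator


@dataclass
class ReadBatch:
    """A columnar set of reads (ids, sequences, per-base qualities)."""

    ids: list[str] = field(default_factory=list)
    seqs: list[str] = field(default_factory=list)
    quals: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seqs)

    def __iter__(self) -> Iterator[tuple[str, str, np.ndarray]]:
        return iter(zip(self.ids, self.seqs, self.quals))

    def append(self, rid: str, seq: str, qual: np.ndarray) -> None:
        self.ids.append(rid)
        self.seqs.append(seq)
        self.quals.append(qual)


def _open(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> ReadBatch:
    batch = ReadBatch()
    with _open(path) as handle:
        for idx, (title, seq, qual) in enumerate(FastqGeneralIterator(handle)):
            if len(seq) != len(qual):
                raise ValueError(f"malformed FASTQ record #{idx} ({title.split()[0]})")
            batch.append(
                title.split()[0],
                seq.upper(),
                np.frombuffer(qual.encode("ascii"), np.uint8) - 33,
            )
    return batch


def write_fastq(batch: ReadBatch, path: str | Path) -> None:
    with _open(path, "wt") as handle:
        for rid, seq, qual in batch:
            qstr = (qual.astype(np.uint8) + 33).tobytes().decode("ascii")
            handle.write(f"@{rid}\n{seq}\n+\n{qstr}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    with _open(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with _open(path, "wt") as handle:
        for name, seq in seqs.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_bedgraph(path: str | Path, length: int | None = None) -> dict[str, np.ndarray]:
    """Load bedGraph coverage into dense per-chromosome tracks."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": int, "end": int, "value": float},
    )
    tracks: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        size = length if length is not None else int(sub["end"].max())
        track = np.zeros(size, dtype=float)
        for start, end, value in zip(sub["start"], sub["end"], sub["value"]):
            track[start:end] = value
        tracks[chrom] = track
    return tracks


def write_bed(intervals: list[tuple[int, int]], path: str | Path, chrom: str = "track", name: str = "enriched") -> None:
    with open(path, "w") as handle:
        for i, (start, end) in enumerate(intervals):
            handle.write(f"{chrom}\t{start}\t{end}\t{name}_{i + 1}\n")
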