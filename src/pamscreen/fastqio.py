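"""Minimal FASTQ records and Phred+33 I/O (Biopython-backed parsing)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator


@dataclass(frozen=True)
class FastqRecord:
    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"record {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    """Write 4-line FASTQ, Phred+33. An empty record list yields an empty,
    valid file."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n")


def iter_fastq(path: str | Path) -> Iterator[FastqRecord]:
    """Stream records from a FASTQ file; malformed input raises with the
    approximate line number."""
    n = 0
    with open(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                n += 1
                yield FastqRecord(id=title.split()[0], seq=seq, qual=qual)
        except ValueError as exc:
            raise ValueError(
                f"{path}: malformed FASTQ near line {4 * n + 1}: {exc}"
            ) from exc


def read_fastq(path: str | Path) -> list[FastqRecord]:
    return list(iter_fastq(path))
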