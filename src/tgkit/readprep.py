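"""Adapter/quality trimming and pair-length filtering for the WGS library.

The recipe mirrors the preprocessing applied to the sequenced library:
3' adapter read-through is removed first (exact suffix/prefix match), then
low-quality bases (q < 16) are stripped from both ends, and finally any pair
in which either mate ended up shorter than 36 nt is discarded.  End-trimming
strips bases from each end until the first/last base meets the quality
threshold; interior bases are never touched, so the output is always a
contiguous substring of the input and trimming is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

# TruSeq universal adapter as read into the 3' end on short fragments.
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"


@dataclass
class ReadRecord:
    """A read with per-base Phred qualities (same length as the sequence)."""

    id: str
    seq: str
    qual: np.ndarray

    def __post_init__(self) -> None:
        self.qual = np.asarray(self.qual, dtype=np.int16)
        if len(self.seq) != len(self.qual):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class PairFilterParams:
    q_min: int = 16
    min_len: int = 36
    adapter: str = DEFAULT_ADAPTER
    min_adapter_overlap: int = 5

    def __post_init__(self) -> None:
        if self.q_min < 0 or self.min_len < 1:
            raise ValueError("q_min must be >= 0 and min_len >= 1")


@dataclass
class FilterReport:
    pairs_in: int = 0
    pairs_kept: int = 0
    pairs_dropped: int = 0

    def to_tsv(self, path: str | Path) -> None:
        Path(path).write_text(
            "pairs_in\tpairs_kept\tpairs_dropped\n"
            f"{self.pairs_in}\t{self.pairs_kept}\t{self.pairs_dropped}\n"
        )


def _adapter_overlap(seq: str, adapter: str, min_overlap: int) -> int:
    """Length of the longest read suffix that equals an adapter prefix."""
    for ov in range(min(len(seq), len(adapter)), min_overlap - 1, -1):
        if seq.endswith(adapter[:ov]):
            return ov
    return 0


def trim_read(read: ReadRecord, params: PairFilterParams | None = None) -> ReadRecord:
    """Adapter-trim the 3' end, then strip low-quality bases from both ends.

    May return an empty read; the pair filter deals with those.
    """
    params = params or PairFilterParams()
    seq, qual = read.seq, read.qual
    ov = _adapter_overlap(seq, params.adapter, params.min_adapter_overlap)
    if ov:
        seq, qual = seq[:-ov], qual[:-ov]
    good = qual >= params.q_min
    if not good.any():
        return ReadRecord(read.id, "", np.empty(0, dtype=np.int16))
    lo = int(np.argmax(good))
    hi = len(good) - int(np.argmax(good[::-1]))
    return ReadRecord(read.id, seq[lo:hi], qual[lo:hi])


def filter_pairs(
    pairs: Iterable[tuple[ReadRecord, ReadRecord]],
    params: PairFilterParams | None = None,
) -> tuple[list[tuple[ReadRecord, ReadRecord]], FilterReport]:
    """Keep pairs in which both mates are at least ``min_len`` long."""
    params = params or PairFilterParams()
    report = FilterReport()
    kept: list[tuple[ReadRecord, ReadRecord]] = []
    for r1, r2 in pairs:
        report.pairs_in += 1
        if len(r1) >= params.min_len and len(r2) >= params.min_len:
            kept.append((r1, r2))
            report.pairs_kept += 1
        else:
            report.pairs_dropped += 1
    return kept, report


def trim_and_filter(
    reads1: Sequence[ReadRecord],
    reads2: Sequence[ReadRecord],
    params: PairFilterParams | None = None,
) -> tuple[list[tuple[ReadRecord, ReadRecord]], FilterReport]:
    """Trim both mates of every pair, then apply the pair-length filter."""
    if len(reads1) != len(reads2):
        raise ValueError("mismatched mate stream lengths")
    params = params or PairFilterParams()
    trimmed = ((trim_read(r1, params), trim_read(r2, params)) for r1, r2 in zip(reads1, reads2))
    return filter_pairs(trimmed, params)


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    """Write Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for r in reads:
            q = "".join(chr(v + 33) for v in r.qual)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{q}\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            ReadRecord(rec.id, str(rec.seq), np.array(rec.letter_annotations["phred_quality"]))
        )
    return out
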