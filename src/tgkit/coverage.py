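"""Aligned-base (M-base) depth over reference intervals."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .mapper import AlignmentRecord


def depth_array(
    records: Iterable[AlignmentRecord], contig: str, start: int, end: int
) -> np.ndarray:
    """Per-position M-base depth over [start, end] (1-based inclusive)."""
    if end < start:
        raise ValueError("end < start")
    diff = np.zeros(end - start + 2, dtype=np.int64)
    for rec in records:
        if rec.contig != contig:
            continue
        s = max(rec.pos, start)
        e = min(rec.m_end, end)
        if s <= e:
            diff[s - start] += 1
            diff[e - start + 1] -= 1
    return np.cumsum(diff[:-1])


def mean_depth(
    records: Sequence[AlignmentRecord], contig: str, start: int, end: int
) -> float:
    return float(depth_array(records, contig, start, end).mean())
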