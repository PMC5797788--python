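"""Junction microhomology measurement.

When an insert terminus repeats the chromosomal sequence adjacent to its
junction, the exact breakpoint is ambiguous within that shared tract and
read alignments extend through it.  All coordinates here are 1-based local
positions on the chromosomal window; ``insert`` is the inserted unit in the
orientation in which it sits on the chromosome.

Convention used throughout the package: the shared tract is attributed to
the insert, so ``left_bp`` is the last retained chromosomal base before the
insertion and ``right_bp`` the first retained base after it.  The functions
come in two flavours per junction: one anchored at an observed soft-clip
consensus (what split reads give you) and one anchored at a breakpoint
(what the convention defines).  On a consistent junction they agree.
"""

from __future__ import annotations

DEFAULT_MAX_H = 30


def homology_at_left_clip(insert: str, chrom: str, clip: int, max_h: int = DEFAULT_MAX_H) -> int:
    """Largest k with insert[1..k] == chrom[clip-k+1..clip].

    ``clip`` is the consensus position of the last chromosome-aligned base of
    reads entering the insert from the left flank.
    """
    best = 0
    for k in range(1, min(max_h, clip, len(insert)) + 1):
        if insert[:k] == chrom[clip - k:clip]:
            best = k
    return best


def homology_after(insert: str, chrom: str, left_bp: int, max_h: int = DEFAULT_MAX_H) -> int:
    """Largest k with insert[1..k] == chrom[left_bp+1..left_bp+k]."""
    best = 0
    for k in range(1, min(max_h, len(chrom) - left_bp, len(insert)) + 1):
        if insert[:k] == chrom[left_bp:left_bp + k]:
            best = k
    return best


def homology_at_right_clip(insert: str, chrom: str, clip: int, max_h: int = DEFAULT_MAX_H) -> int:
    """Largest k with insert[-k:] == chrom[clip..clip+k-1].

    ``clip`` is the consensus position of the first chromosome-aligned base of
    reads leaving the insert into the right flank.
    """
    best = 0
    for k in range(1, min(max_h, len(chrom) - clip + 1, len(insert)) + 1):
        if insert[-k:] == chrom[clip - 1:clip - 1 + k]:
            best = k
    return best


def homology_before(insert: str, chrom: str, right_bp: int, max_h: int = DEFAULT_MAX_H) -> int:
    """Largest k with insert[-k:] == chrom[right_bp-k..right_bp-1]."""
    best = 0
    for k in range(1, min(max_h, right_bp - 1, len(insert)) + 1):
        if insert[-k:] == chrom[right_bp - 1 - k:right_bp - 1]:
            best = k
    return best
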