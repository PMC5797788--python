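"""SAM text input/output via pysam.

The integration caller consumes :class:`~tgkit.mapper.AlignmentRecord`
streams; these converters let any external aligner's SAM output substitute
for the built-in mapper, and let its output be inspected with standard
tools.  Only the fields the pipeline uses are round-tripped (position,
strand, CIGAR M/S structure, MAPQ, proper-pair flag, NM).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .mapper import AlignmentRecord
from .synthgen.genome import ReferenceSet

_CIG = re.compile(r"(\d+)([MIDNSHP=X])")


def write_sam(
    records: Iterable[AlignmentRecord],
    refs: ReferenceSet | Sequence[tuple[str, int]],
    path: str | Path,
) -> None:
    """Write records as SAM with @SQ lines from the reference set."""
    if isinstance(refs, ReferenceSet):
        sq = [(c.name, len(c)) for c in refs.contigs]
    else:
        sq = list(refs)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": n, "LN": ln} for n, ln in sq],
        }
    )
    names = [n for n, _ in sq]
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(header)
            a.query_name = rec.qname
            a.query_sequence = rec.seq or None
            flag = 0x1 | (0x40 if rec.mate == 1 else 0x80)
            if not rec.is_mapped:
                a.flag = flag | 0x4
                out.write(a)
                continue
            if rec.strand == "-":
                flag |= 0x10
            if rec.proper_pair:
                flag |= 0x2
            if not rec.primary:
                flag |= 0x100
            a.flag = flag
            a.reference_id = names.index(rec.contig)
            a.reference_start = rec.pos - 1
            a.mapping_quality = rec.mapq
            cig = []
            if rec.lclip:
                cig.append((4, rec.lclip))
            cig.append((0, rec.mlen))
            if rec.rclip:
                cig.append((4, rec.rclip))
            a.cigartuples = cig
            a.set_tag("NM", rec.nm)
            out.write(a)


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Parse SAM/BAM into alignment records (soft-clip structure preserved;
    gapped CIGARs are reduced to their reference span for depth purposes)."""
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for a in fh:
            if a.is_secondary or a.is_supplementary:
                continue
            mate = 2 if a.is_read2 else 1
            if a.is_unmapped:
                out.append(AlignmentRecord(a.query_name, mate, None,
                                           seq=a.query_sequence or ""))
                continue
            lclip = rclip = 0
            cig = a.cigartuples or []
            if cig and cig[0][0] in (4, 5):
                lclip = cig[0][1] if cig[0][0] == 4 else 0
                cig = cig[1:]
            if cig and cig[-1][0] in (4, 5):
                rclip = cig[-1][1] if cig[-1][0] == 4 else 0
                cig = cig[:-1]
            mlen = sum(n for op, n in cig if op in (0, 7, 8, 2, 3))
            out.append(
                AlignmentRecord(
                    qname=a.query_name,
                    mate=mate,
                    contig=a.reference_name,
                    pos=a.reference_start + 1,
                    strand="-" if a.is_reverse else "+",
                    lclip=lclip,
                    mlen=mlen,
                    rclip=rclip,
                    nm=int(a.get_tag("NM")) if a.has_tag("NM") else 0,
                    mapq=a.mapping_quality,
                    proper_pair=a.is_proper_pair,
                    seq=a.query_sequence or "",
                )
            )
    return out
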