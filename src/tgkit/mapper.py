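"""Minimal seed-and-extend paired-end aligner producing SAM-style records.

Adequate for the desk-scale synthetic references; at real scale any external
aligner can substitute, since the downstream caller consumes SAM (see
:mod:`tgkit.samio`).  The algorithm: exact k-mer seeds (k = 21) at three
offsets per strand, candidate diagonals deduplicated, then ungapped
extension (match +1, mismatch -4) along each diagonal keeping the
best-scoring contiguous window.  Terminal segments that cannot extend are
soft-clipped when they are at least ``min_clip`` bases long; shorter tails
are absorbed into the match (counting mismatches), as read-end sequencing
errors would be.  Alignments are gap-free, so CIGARs use only M and S.

The mapping-quality surrogate is binary: 60 for a unique best placement, 0
when the best score is tied across loci — downstream logic only needs
unique-vs-ambiguous.  Ties are broken deterministically (contig order in the
reference set, then leftmost position).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .dna import decode, encode, revcomp_codes
from .readprep import ReadRecord
from .synthgen.genome import ReferenceSet


@dataclass
class MapParams:
    k: int = 21
    match: int = 1
    mismatch: int = -4
    min_clip: int = 8
    min_score: int = 20
    insert_min: int = 100
    insert_max: int = 700
    max_hits_per_seed: int = 50


@dataclass
class AlignmentRecord:
    """A mapped (or unmapped) read; ``pos`` is the 1-based leftmost mapped
    base, ``seq`` is stored in reference orientation (SAM convention)."""

    qname: str
    mate: int                 # 1 or 2
    contig: str | None
    pos: int = 0
    strand: str = "+"
    lclip: int = 0
    mlen: int = 0
    rclip: int = 0
    nm: int = 0
    mapq: int = 0
    proper_pair: bool = False
    primary: bool = True
    seq: str = ""

    @property
    def is_mapped(self) -> bool:
        return self.contig is not None

    @property
    def m_end(self) -> int:
        """1-based position of the last aligned base."""
        return self.pos + self.mlen - 1

    @property
    def cigar(self) -> str:
        if not self.is_mapped:
            return "*"
        parts = []
        if self.lclip:
            parts.append(f"{self.lclip}S")
        parts.append(f"{self.mlen}M")
        if self.rclip:
            parts.append(f"{self.rclip}S")
        return "".join(parts)

    @property
    def clipped_prefix(self) -> str:
        return self.seq[: self.lclip]

    @property
    def clipped_suffix(self) -> str:
        return self.seq[len(self.seq) - self.rclip:] if self.rclip else ""


class SeedIndex:
    """Sorted k-mer -> (contig, position) index over all contigs."""

    def __init__(self, references: ReferenceSet | Sequence[tuple[str, str]], k: int = 21):
        if isinstance(references, ReferenceSet):
            items = [(c.name, c.sequence) for c in references.contigs]
        else:
            items = list(references)
        self.k = k
        self.names = [n for n, _ in items]
        self.seqs = [encode(s) for _, s in items]
        if any(s.size < k for s in self.seqs):
            raise ValueError(f"k={k} exceeds the shortest contig length")
        self._pow = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
        kmer_parts, cidx_parts, pos_parts = [], [], []
        for ci, codes in enumerate(self.seqs):
            win = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.int64)
            kmers = win @ self._pow
            kmer_parts.append(kmers)
            cidx_parts.append(np.full(kmers.size, ci, dtype=np.int32))
            pos_parts.append(np.arange(kmers.size, dtype=np.int32))
        kmers = np.concatenate(kmer_parts)
        order = np.argsort(kmers, kind="stable")
        self.kmers = kmers[order]
        self.cidx = np.concatenate(cidx_parts)[order]
        self.cpos = np.concatenate(pos_parts)[order]

    def lookup(self, kmer: int) -> tuple[np.ndarray, np.ndarray]:
        lo = int(np.searchsorted(self.kmers, kmer, side="left"))
        hi = int(np.searchsorted(self.kmers, kmer, side="right"))
        return self.cidx[lo:hi], self.cpos[lo:hi]

    def encode_kmer(self, codes: np.ndarray) -> int:
        return int(codes.astype(np.int64) @ self._pow)


def build_index(refs: ReferenceSet | Sequence[tuple[str, str]], k: int = 21) -> SeedIndex:
    """Complete k-mer position index over all contigs (error if k exceeds a
    contig length)."""
    return SeedIndex(refs, k)


def _best_window(eq: np.ndarray, match: int, mismatch: int) -> tuple[int, int, int]:
    """Best-scoring contiguous window of a match/mismatch vector
    (Kadane, leftmost maximal); returns (start, end_inclusive, score)."""
    s = np.where(eq, match, mismatch).astype(np.int64)
    cs = np.cumsum(s)
    prefix = np.concatenate(([0], cs))
    runmin = np.minimum.accumulate(prefix)
    gains = cs - runmin[:-1]
    end = int(np.argmax(gains))
    score = int(gains[end])
    start = int(np.argmax(prefix[: end + 1] == runmin[end]))
    return start, end, score


def _extend(codes: np.ndarray, ref: np.ndarray, diag: int, p: MapParams):
    """Ungapped extension of a read along one diagonal; returns
    (score, first_aligned, last_aligned, nm) in read coordinates, or None."""
    L = codes.size
    lo = max(0, -diag)
    hi = min(L, ref.size - diag)
    if hi - lo < p.k:
        return None
    eq = codes[lo:hi] == ref[diag + lo: diag + hi]
    a_rel, b_rel, _ = _best_window(eq, p.match, p.mismatch)
    a, b = lo + a_rel, lo + b_rel
    # Absorb sub-threshold terminal tails where the contig allows it.
    if 0 < a < p.min_clip:
        a = lo
    if 0 < (L - 1 - b) < p.min_clip:
        b = hi - 1
    nm = int((~eq[a - lo: b - lo + 1]).sum())
    score = (b - a + 1 - nm) * p.match + nm * p.mismatch
    return score, a, b, nm


def _seed_offsets(L: int, k: int) -> list[int]:
    return sorted({0, (L - k) // 2, L - k})


def _align_read(read: ReadRecord, index: SeedIndex, p: MapParams, mate: int) -> AlignmentRecord:
    codes = encode(read.seq)
    L = codes.size
    if L < p.k:
        return AlignmentRecord(read.id, mate, None, seq=read.seq)
    rc = revcomp_codes(codes)
    cands: set[tuple[int, int, str]] = set()
    for strand, cs in (("+", codes), ("-", rc)):
        for off in _seed_offsets(L, p.k):
            ci, cp = index.lookup(index.encode_kmer(cs[off:off + p.k]))
            if ci.size == 0 or ci.size > p.max_hits_per_seed:
                continue
            for c, q in zip(ci, cp):
                cands.add((int(c), int(q) - off, strand))

    results = []
    for ci, diag, strand in sorted(cands):
        cs = codes if strand == "+" else rc
        res = _extend(cs, index.seqs[ci], diag, p)
        if res is not None:
            score, a, b, nm = res
            results.append((score, ci, diag, strand, a, b, nm))
    if not results:
        return AlignmentRecord(read.id, mate, None, seq=read.seq)
    top = max(r[0] for r in results)
    if top < p.min_score:
        return AlignmentRecord(read.id, mate, None, seq=read.seq)
    # Distinct placements achieving the top score (different diagonals can
    # collapse onto one window after clipping, so dedupe by final placement).
    tied = {(r[1], r[2] + r[4], r[3], r[2] + r[5]): r for r in results if r[0] == top}
    # Deterministic tie-break: contig order in the index, then leftmost.
    score, ci, diag, strand, a, b, nm = min(
        tied.values(), key=lambda r: (r[1], r[2] + r[4], r[3])
    )
    n_ties = len(tied)
    cs = codes if strand == "+" else rc
    return AlignmentRecord(
        qname=read.id,
        mate=mate,
        contig=index.names[ci],
        pos=diag + a + 1,
        strand=strand,
        lclip=a,
        mlen=b - a + 1,
        rclip=L - 1 - b,
        nm=nm,
        mapq=0 if n_ties > 1 else 60,
        seq=decode(cs),
    )


def map_pair(
    r1: ReadRecord, r2: ReadRecord, index: SeedIndex, params: MapParams | None = None
) -> tuple[AlignmentRecord, AlignmentRecord]:
    """Map one pair; sets the proper-pair flag from insert plausibility
    (same contig, opposite strands, span within the configured range)."""
    p = params or MapParams()
    a1 = _align_read(r1, index, p, 1)
    a2 = _align_read(r2, index, p, 2)
    if a1.is_mapped and a2.is_mapped and a1.contig == a2.contig and a1.strand != a2.strand:
        span = max(a1.m_end, a2.m_end) - min(a1.pos, a2.pos) + 1
        if p.insert_min <= span <= p.insert_max:
            a1.proper_pair = a2.proper_pair = True
    return a1, a2


def map_pairs(
    pairs: Iterable[tuple[ReadRecord, ReadRecord]],
    index: SeedIndex,
    params: MapParams | None = None,
) -> list[AlignmentRecord]:
    """Map a stream of pairs; returns a flat record list (two per pair)."""
    p = params or MapParams()
    out: list[AlignmentRecord] = []
    for r1, r2 in pairs:
        a1, a2 = map_pair(r1, r2, index, p)
        out.append(a1)
        out.append(a2)
    return out
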