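"""Recover a multi-copy transgene integration site from paired-end alignments.

The chain of evidence mirrors how the insertion was found in the sequenced
genome:

1. *Informative pairs* — every pair with a mate on the transgene contig or
   inside the endogenous Arc locus (ambiguous mapq-0 hits included: the
   transgene carries the Arc cDNA, so that ambiguity is the point).
2. *Candidate region* — the densest cluster of the informative pairs'
   off-locus counterpart mates, padded to a fixed width (8 kb by default).
3. *Coverage gap* — the flanking deletion shows up as a run of zero M-base
   depth (homozygous) or of depth well below the flank median (hemizygous).
4. *Breakpoints* — soft-clipped reads at the gap edges are matched to the
   transgene termini; the clip-position consensus and the maximal shared
   tract between the insert terminus and the adjacent reference sequence
   give single-base breakpoints plus the junction microhomologies.
   Homology bases are attributed to the transgene: ``left_bp`` is the last
   retained chromosomal base, ``right_bp`` the first retained base, and
   ``deletion = right_bp - left_bp - 1``.
5. *Secondary scan* — clusters of transgene-anchored mates anywhere else in
   the genome reveal additional integrations.

An in-silico PCR utility predicts junction/WT amplicons for confirmation
primer sets.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .coverage import depth_array
from .dna import revcomp
from .mapper import AlignmentRecord
from .microhomology import (
    homology_after,
    homology_at_left_clip,
    homology_at_right_clip,
    homology_before,
)
from .synthgen.genome import ReferenceSet


@dataclass
class CallerConfig:
    cluster_window: int = 4_000     # bp, counterpart-mate clustering; wide
                                    # enough to merge both junction clusters
                                    # (deletion + insert-size spread)
    pad_to: int = 8_000             # bp, candidate-region width
    min_cluster: int = 4            # pairs needed to accept a cluster
    locus_pad: int = 2_000          # bp, halo around the Arc locus to ignore
    depth_max: int = 0              # max depth inside a homozygous gap
    min_gap_len: int = 500          # bp
    drop_frac: float = 0.75         # hemizygous: smoothed depth < frac * median
    homo_frac: float = 0.1          # zygosity call threshold on gap depth
    min_support: int = 2            # junction reads per side for confidence
    clip_min: int = 8               # minimum informative soft-clip length
    edge_margin: int = 300          # bp, clip harvest window around gap edges
    terminus_margin: int = 30       # bp, "at a transgene terminus" tolerance
    anchor_len: int = 25            # bp, exact anchor for locating clips
    max_h: int = 30                 # maximal microhomology considered
    secondary_min: int = 3          # pairs per secondary-site cluster
    known_site_pad: int = 5_000     # bp


@dataclass
class InformativePairSet:
    pairs: list[tuple[AlignmentRecord, AlignmentRecord]]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class CandidateRegion:
    chrom: str
    start: int            # global, 1-based inclusive
    end: int
    contig: str
    start_local: int
    end_local: int
    n_support: int = 0


@dataclass
class CoverageGap:
    contig: str
    start_local: int      # 1-based inclusive zero/low-depth run
    end_local: int
    start: int            # global
    end: int
    length: int
    flank_median: float
    mean_depth: float
    mode: str


@dataclass
class JunctionEvidence:
    qname: str
    side: str             # 'left' | 'right'
    clip_pos_local: int
    clipped_seq: str
    orientation: str
    source: str           # 'flank' (chromosome-anchored) | 'transgene'
    bp_vote_local: int


@dataclass
class SecondarySite:
    chrom: str
    position: int         # global, cluster centre
    n_pairs: int


@dataclass
class IntegrationCall:
    chrom: str
    left_bp: int          # global; last retained base of the left flank
    right_bp: int         # global; first retained base of the right flank
    h_left: int
    h_right: int
    orientation: str
    support_left: int
    support_right: int
    zygosity: str
    low_confidence: bool
    region: CandidateRegion
    gap: CoverageGap
    secondary_sites: list[SecondarySite] = field(default_factory=list)

    @property
    def deletion_length(self) -> int:
        return self.right_bp - self.left_bp - 1

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "left_bp": self.left_bp,
            "right_bp": self.right_bp,
            "deletion_length": self.deletion_length,
            "h_left": self.h_left,
            "h_right": self.h_right,
            "orientation": self.orientation,
            "support_left": self.support_left,
            "support_right": self.support_right,
            "zygosity": self.zygosity,
            "low_confidence": self.low_confidence,
            "secondary_sites": [
                {"chrom": s.chrom, "position": s.position, "n_pairs": s.n_pairs}
                for s in self.secondary_sites
            ],
        }


# ---------------------------------------------------------------------------


def _arc_locus_local(refs: ReferenceSet) -> tuple[str, int, int]:
    chrom, g0, g1 = refs.arc_locus
    c = refs.contig(chrom)
    return c.name, g0 - c.global_start + 1, g1 - c.global_start + 1


def _pair_iter(records: Iterable[AlignmentRecord]):
    by_name: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for rec in records:
        by_name[rec.qname].append(rec)
    for name, recs in by_name.items():
        m1 = next((r for r in recs if r.mate == 1), None)
        m2 = next((r for r in recs if r.mate == 2), None)
        if m1 is not None and m2 is not None:
            yield m1, m2


def _in_interval(rec: AlignmentRecord, contig: str, lo: int, hi: int) -> bool:
    return rec.is_mapped and rec.contig == contig and rec.pos <= hi and rec.m_end >= lo


def is_informative(rec: AlignmentRecord, refs: ReferenceSet, pad: int = 0) -> bool:
    """Mate criterion: mapped to the transgene contig or the Arc locus."""
    if not rec.is_mapped:
        return False
    if rec.contig == refs.transgene_name:
        return True
    contig, lo, hi = _arc_locus_local(refs)
    return _in_interval(rec, contig, lo - pad, hi + pad)


def extract_informative_pairs(
    records: Iterable[AlignmentRecord], refs: ReferenceSet
) -> InformativePairSet:
    """Pairs in which at least one mate satisfies the informative criterion."""
    if not any(c.name == refs.transgene_name for c in refs.contigs):
        raise ValueError(f"unknown transgene contig {refs.transgene_name!r}")
    pairs = [
        (m1, m2)
        for m1, m2 in _pair_iter(records)
        if is_informative(m1, refs) or is_informative(m2, refs)
    ]
    return InformativePairSet(pairs)


def _densest_cluster(positions: list[int], window: int) -> tuple[int, int]:
    """(count, centre) of the densest fixed-width window over sorted points."""
    pos = sorted(positions)
    best_n, best_centre = 0, 0
    j = 0
    for i in range(len(pos)):
        if j < i:
            j = i
        while j + 1 < len(pos) and pos[j + 1] <= pos[i] + window:
            j += 1
        n = j - i + 1
        if n > best_n:
            best_n = n
            best_centre = int(np.median(pos[i:j + 1]))
    return best_n, best_centre


def locate_candidate_region(
    pairs: InformativePairSet, refs: ReferenceSet, config: CallerConfig | None = None
) -> CandidateRegion | None:
    """Densest cluster of non-transgene, non-Arc-locus counterpart mates,
    padded symmetrically to ``pad_to``; None when no cluster qualifies
    (e.g. wild-type input)."""
    cfg = config or CallerConfig()
    arc_contig, arc_lo, arc_hi = _arc_locus_local(refs)
    counterparts: dict[str, list[int]] = defaultdict(list)
    for m1, m2 in pairs.pairs:
        for rec in (m1, m2):
            if not rec.is_mapped or rec.contig == refs.transgene_name:
                continue
            if _in_interval(rec, arc_contig, arc_lo - cfg.locus_pad, arc_hi + cfg.locus_pad):
                continue
            counterparts[rec.contig].append((rec.pos + rec.m_end) // 2)
    best = None
    for contig, positions in sorted(counterparts.items()):
        n, centre = _densest_cluster(positions, cfg.cluster_window)
        if best is None or n > best[0]:
            best = (n, contig, centre)
    if best is None or best[0] < cfg.min_cluster:
        return None
    n, contig_name, centre = best
    contig = refs.contig(contig_name)
    width = min(cfg.pad_to, len(contig))
    start = max(1, min(centre - width // 2 + 1, len(contig) - width + 1))
    end = start + width - 1
    return CandidateRegion(
        chrom=contig.chrom,
        start=refs.local_to_global(contig_name, start),
        end=refs.local_to_global(contig_name, end),
        contig=contig_name,
        start_local=start,
        end_local=end,
        n_support=n,
    )


def detect_coverage_gap(
    records: Sequence[AlignmentRecord],
    region: CandidateRegion,
    refs: ReferenceSet,
    config: CallerConfig | None = None,
    mode: str = "homozygous",
) -> CoverageGap | None:
    """Longest qualifying low-depth run inside the candidate region.

    ``homozygous`` mode looks for per-base depth <= ``depth_max`` (0 by
    default); ``depth_drop`` mode, for hemizygous deletions, smooths the
    depth over a ``min_gap_len`` window first (per-base depth at ~13x is far
    too noisy to hold a sub-median run together) and looks for smoothed
    depth below ``drop_frac`` x the region median.  Returns None when no run
    reaches ``min_gap_len``.
    """
    cfg = config or CallerConfig()
    depth = depth_array(records, region.contig, region.start_local, region.end_local)
    flank_median = float(np.median(depth))
    if mode == "homozygous":
        mask = depth <= cfg.depth_max
    elif mode == "depth_drop":
        if flank_median == 0:
            return None
        from scipy.ndimage import uniform_filter1d

        smoothed = uniform_filter1d(depth.astype(float), cfg.min_gap_len, mode="nearest")
        mask = smoothed < cfg.drop_frac * flank_median
    else:
        raise ValueError("mode must be 'homozygous' or 'depth_drop'")

    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    runs = [(s, e - 1) for s, e in zip(edges[::2], edges[1::2])]
    runs = [(s, e) for s, e in runs if e - s + 1 >= cfg.min_gap_len]
    if not runs:
        return None
    s, e = max(runs, key=lambda r: r[1] - r[0])
    start_local = region.start_local + int(s)
    end_local = region.start_local + int(e)
    return CoverageGap(
        contig=region.contig,
        start_local=start_local,
        end_local=end_local,
        start=refs.local_to_global(region.contig, start_local),
        end=refs.local_to_global(region.contig, end_local),
        length=end_local - start_local + 1,
        flank_median=flank_median,
        mean_depth=float(depth[s:e + 1].mean()),
        mode=mode,
    )


# --------------------------- breakpoint resolution -------------------------


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _match_terminus_start(clip: str, ins: str, max_h: int) -> int | None:
    """Offset o (bases of the insert already absorbed by the chromosomal
    alignment) such that the clipped sequence continues ins[o:]; None if no
    offset matches with <= 1 mismatch."""
    w = min(len(clip), 40)
    for o in range(0, max_h + 1):
        if _mismatches(clip[:w], ins[o:o + w]) <= 1:
            return o
    return None


def _match_terminus_end(clip: str, ins: str, max_h: int) -> int | None:
    """Like :func:`_match_terminus_start` for reads entering the right flank:
    the clipped prefix should end with ins[:L-o] for some absorbed o."""
    w = min(len(clip), 40)
    for o in range(0, max_h + 1):
        seg = ins[len(ins) - o - w:len(ins) - o]
        if _mismatches(clip[-w:], seg) <= 1:
            return o
    return None


def _find_start(chrom: str, s: str, anchor_len: int) -> int | None:
    """1-based position where s begins in chrom (unique exact anchor)."""
    if len(s) < anchor_len:
        return None
    anchor = s[:anchor_len]
    i = chrom.find(anchor)
    if i < 0 or chrom.find(anchor, i + 1) >= 0:
        return None
    return i + 1


def _find_end(chrom: str, s: str, anchor_len: int) -> int | None:
    """1-based position where s ends in chrom (unique exact anchor)."""
    if len(s) < anchor_len:
        return None
    anchor = s[-anchor_len:]
    i = chrom.find(anchor)
    if i < 0 or chrom.find(anchor, i + 1) >= 0:
        return None
    return i + anchor_len


def _consensus(votes: Counter) -> tuple[int | None, int]:
    if not votes:
        return None, 0
    pos, n = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    return pos, n


@dataclass
class BreakpointResult:
    left_bp_local: int
    right_bp_local: int
    h_left: int
    h_right: int
    orientation: str
    support_left: int
    support_right: int
    low_confidence: bool
    evidence: list[JunctionEvidence]


def resolve_breakpoints(
    records: Sequence[AlignmentRecord],
    gap: CoverageGap,
    refs: ReferenceSet,
    config: CallerConfig | None = None,
) -> BreakpointResult:
    """Single-base breakpoints and microhomologies from split reads.

    Junction evidence comes from both directions: reads anchored on the
    chromosome whose clipped tail matches a transgene terminus, and reads
    anchored at a transgene terminus whose clipped tail locates uniquely in
    the candidate chromosome.  Each read casts one (breakpoint, orientation)
    vote; the consensus is the best-supported position (ties broken toward
    more reads, then leftmost).  The final microhomology is the maximal
    shared tract between the oriented insert terminus and the reference
    sequence adjacent to the consensus breakpoint.
    """
    cfg = config or CallerConfig()
    chrom = refs.seq(gap.contig)
    tg = refs.transgene_seq
    tg_name = refs.transgene_name
    ins_by_ori = {"+": tg, "-": revcomp(tg)}
    # Smoothed (depth_drop) gap edges sit up to half the smoothing window
    # inside the true deletion; widen the clip-harvest window accordingly.
    margin = cfg.edge_margin + (cfg.min_gap_len if gap.mode == "depth_drop" else 0)

    vote_left: Counter = Counter()
    vote_right: Counter = Counter()
    ori_votes: Counter = Counter()
    evidence: list[JunctionEvidence] = []
    n_unmatched = 0

    for rec in records:
        if not rec.is_mapped:
            continue
        if rec.contig == gap.contig:
            # Chromosome-anchored split reads at the gap edges.
            p = rec.m_end
            if rec.rclip >= cfg.clip_min and abs(p - (gap.start_local - 1)) <= margin:
                clip = rec.clipped_suffix
                matched = False
                for ori, ins in ins_by_ori.items():
                    if _match_terminus_start(clip, ins, cfg.max_h) is not None:
                        h_p = homology_at_left_clip(ins, chrom, p, cfg.max_h)
                        vote_left[p - h_p] += 1
                        ori_votes[ori] += 1
                        evidence.append(JunctionEvidence(
                            rec.qname, "left", p, clip, ori, "flank", p - h_p))
                        matched = True
                        break
                if not matched:
                    n_unmatched += 1
            q = rec.pos
            if rec.lclip >= cfg.clip_min and abs(q - (gap.end_local + 1)) <= margin:
                clip = rec.clipped_prefix
                matched = False
                for ori, ins in ins_by_ori.items():
                    if _match_terminus_end(clip, ins, cfg.max_h) is not None:
                        h_q = homology_at_right_clip(ins, chrom, q, cfg.max_h)
                        vote_right[q + h_q] += 1
                        ori_votes[ori] += 1
                        evidence.append(JunctionEvidence(
                            rec.qname, "right", q, clip, ori, "flank", q + h_q))
                        matched = True
                        break
                if not matched:
                    n_unmatched += 1
        elif rec.contig == tg_name:
            # Transgene-terminus-anchored reads clipped into the chromosome.
            if rec.lclip >= cfg.clip_min and rec.pos <= cfg.terminus_margin:
                clip = rec.clipped_prefix
                e = _find_end(chrom, clip, cfg.anchor_len)
                if e is not None:
                    vote_left[e] += 1
                    ori_votes["+"] += 1
                    evidence.append(JunctionEvidence(
                        rec.qname, "left", e, clip, "+", "transgene", e))
                else:
                    b = _find_start(chrom, revcomp(clip), cfg.anchor_len)
                    if b is not None:
                        vote_right[b] += 1
                        ori_votes["-"] += 1
                        evidence.append(JunctionEvidence(
                            rec.qname, "right", b, clip, "-", "transgene", b))
            if rec.rclip >= cfg.clip_min and rec.m_end >= len(tg) - cfg.terminus_margin:
                clip = rec.clipped_suffix
                b = _find_start(chrom, clip, cfg.anchor_len)
                if b is not None:
                    vote_right[b] += 1
                    ori_votes["+"] += 1
                    evidence.append(JunctionEvidence(
                        rec.qname, "right", b, clip, "+", "transgene", b))
                else:
                    e = _find_end(chrom, revcomp(clip), cfg.anchor_len)
                    if e is not None:
                        vote_left[e] += 1
                        ori_votes["-"] += 1
                        evidence.append(JunctionEvidence(
                            rec.qname, "left", e, clip, "-", "transgene", e))

    if n_unmatched:
        warnings.warn(
            f"{n_unmatched} clipped reads at the gap edges matched neither "
            "transgene terminus and were discarded",
            stacklevel=2,
        )

    orientation = ori_votes.most_common(1)[0][0] if ori_votes else "+"
    ins = ins_by_ori[orientation]
    left_local, support_left = _consensus(vote_left)
    right_local, support_right = _consensus(vote_right)
    if left_local is None:
        left_local = gap.start_local - 1
    if right_local is None:
        right_local = gap.end_local + 1
    h_left = homology_after(ins, chrom, left_local, cfg.max_h)
    h_right = homology_before(ins, chrom, right_local, cfg.max_h)
    low_confidence = support_left < cfg.min_support or support_right < cfg.min_support
    return BreakpointResult(
        left_bp_local=left_local,
        right_bp_local=right_local,
        h_left=h_left,
        h_right=h_right,
        orientation=orientation,
        support_left=support_left,
        support_right=support_right,
        low_confidence=low_confidence,
        evidence=evidence,
    )


def scan_secondary_integrations(
    records: Sequence[AlignmentRecord],
    refs: ReferenceSet,
    known_sites: Sequence[tuple[str, int]],
    config: CallerConfig | None = None,
) -> list[SecondarySite]:
    """Clusters of transgene-anchored mates outside the known sites and the
    endogenous Arc locus."""
    cfg = config or CallerConfig()
    arc_contig, arc_lo, arc_hi = _arc_locus_local(refs)
    positions: dict[str, list[int]] = defaultdict(list)
    for m1, m2 in _pair_iter(records):
        tg_mates = [r for r in (m1, m2) if r.is_mapped and r.contig == refs.transgene_name]
        others = [r for r in (m1, m2) if r.is_mapped and r.contig != refs.transgene_name]
        if not tg_mates or not others:
            continue
        rec = others[0]
        if _in_interval(rec, arc_contig, arc_lo - cfg.locus_pad, arc_hi + cfg.locus_pad):
            continue
        gpos = refs.local_to_global(rec.contig, (rec.pos + rec.m_end) // 2)
        chrom = refs.contig(rec.contig).chrom
        if any(
            chrom == kc and abs(gpos - kp) <= cfg.known_site_pad for kc, kp in known_sites
        ):
            continue
        positions[rec.contig].append((rec.pos + rec.m_end) // 2)

    sites = []
    for contig, pos in sorted(positions.items()):
        n, centre = _densest_cluster(pos, cfg.cluster_window)
        if n >= cfg.secondary_min:
            sites.append(SecondarySite(
                chrom=refs.contig(contig).chrom,
                position=refs.local_to_global(contig, centre),
                n_pairs=n,
            ))
    return sites


def call_integration(
    records: Sequence[AlignmentRecord],
    refs: ReferenceSet,
    config: CallerConfig | None = None,
) -> IntegrationCall | None:
    """Full pipeline: extraction -> region -> gap -> breakpoints -> call.

    Returns None (a clean no-call) when no candidate region or no coverage
    gap is found, as for wild-type input.
    """
    cfg = config or CallerConfig()
    records = list(records)
    pairs = extract_informative_pairs(records, refs)
    region = locate_candidate_region(pairs, refs, cfg)
    if region is None:
        return None
    gap = detect_coverage_gap(records, region, refs, cfg, mode="homozygous")
    if gap is None:
        gap = detect_coverage_gap(records, region, refs, cfg, mode="depth_drop")
    if gap is None:
        return None
    bp = resolve_breakpoints(records, gap, refs, cfg)
    zygosity = (
        "homozygous"
        if gap.flank_median > 0 and gap.mean_depth < cfg.homo_frac * gap.flank_median
        else "heterozygous"
    )
    left_bp = refs.local_to_global(gap.contig, bp.left_bp_local)
    right_bp = refs.local_to_global(gap.contig, bp.right_bp_local)
    secondary = scan_secondary_integrations(
        records, refs, [(region.chrom, left_bp)], cfg
    )
    return IntegrationCall(
        chrom=region.chrom,
        left_bp=left_bp,
        right_bp=right_bp,
        h_left=bp.h_left,
        h_right=bp.h_right,
        orientation=bp.orientation,
        support_left=bp.support_left,
        support_right=bp.support_right,
        zygosity=zygosity,
        low_confidence=bp.low_confidence,
        region=region,
        gap=gap,
        secondary_sites=secondary,
    )


def insilico_pcr(
    template: str, fwd_primer: str, rev_primer: str, max_len: int = 5_000
) -> list[int]:
    """All amplicon lengths produced on a template by exact primer matches:
    forward primer on the top strand, reverse primer's reverse complement
    downstream within ``max_len``.  Empty list means no product."""
    if not fwd_primer or not rev_primer:
        raise ValueError("primers must be non-empty")
    rc_rev = revcomp(rev_primer)

    def _all_hits(needle: str) -> list[int]:
        hits, i = [], template.find(needle)
        while i >= 0:
            hits.append(i)
            i = template.find(needle, i + 1)
        return hits

    products = []
    for f in _all_hits(fwd_primer):
        for r in _all_hits(rc_rev):
            plen = r + len(rc_rev) - f
            if max(len(fwd_primer), len(rev_primer)) <= plen <= max_len and r >= f:
                products.append(plen)
    return sorted(products)
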