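"""Synthetic reference genome and transgenic haplotypes with known ground truth.

The genome is modelled as three desk-scale windows addressed in global (real
chromosome) coordinates plus the 11,829-bp transgene contig:

* ``chr12`` — 80 kb window around the integration site
  (global = local + 78,100,000, covering Chr12:78,100,001-78,180,000);
* ``chr15`` — 30 kb window containing the endogenous Arc locus
  (Chr15:74,669,000-74,682,000) with the Arc cDNA (5'UTR, ORF, 3'UTR) as an
  explicit gene body;
* ``chr6``  — a single-copy control window holding the gapdh-like normalizer
  locus used by qPCR and read-depth copy-number estimation.

The transgene is promoter (7,000 bp) + Arc 5'UTR (200 bp) + EGFP marker
(750 bp) + Arc ORF (1,200 bp) + Arc 3'UTR (2,679 bp) = 11,829 bp.  The UTRs
and ORF are literal copies of the chr15 gene body — the construct carries
Arc's own cDNA — which reproduces the multi-mapping ambiguity between the
transgene array and the endogenous locus that the integration caller and the
copy-number estimator have to cope with.  Promoter and EGFP are random and
therefore unique anchors.

The transgenic allele replaces chr12 bases (left_bp, right_bp) exclusive with
C tandem copies of the (optionally reverse-complemented) transgene, deleting
right_bp - left_bp - 1 bases.  Microhomology is planted so that the first
h_left bases of the inserted unit equal the first h_left deleted chr12 bases
and its last h_right bases equal the last h_right deleted bases; a repair
loop then resamples a handful of free bases until the measured homology and
the ungapped-extension stop point agree exactly with the planted values, so
the planted scenario is unambiguous by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from ..dna import decode, encode, random_codes, revcomp
from ..microhomology import (
    homology_after,
    homology_at_left_clip,
    homology_at_right_clip,
    homology_before,
)

# Window placement (global 1-based coordinates of the first window base).
CHR12_START = 78_100_001
CHR15_START = 74_660_001
CONTROL_CHROM = "chr6"
CONTROL_START = 125_160_001

DEFAULT_CHR12_LEN = 80_000
DEFAULT_CHR15_LEN = 30_000
DEFAULT_CONTROL_LEN = 150_000

ARC_LOCUS_GLOBAL = (74_669_000, 74_682_000)

TRANSGENE_NAME = "EGFP_Arc_tg"
TRANSGENE_LEN = 11_829
TG_PROMOTER_LEN = 7_000
TG_UTR5_LEN = 200
TG_EGFP_LEN = 750
TG_ORF_LEN = 1_200
TG_UTR3_LEN = TRANSGENE_LEN - (TG_PROMOTER_LEN + TG_UTR5_LEN + TG_EGFP_LEN + TG_ORF_LEN)

# chr15 gene body (local, 1-based inclusive): 5'UTR + ORF + 3'UTR contiguous.
CHR15_GENE_START = 13_801
ARC_CDNA_LEN = TG_UTR5_LEN + TG_ORF_LEN + TG_UTR3_LEN  # 4,079 bp shared per copy

# Control (gapdh-like) locus, local 1-based inclusive.
CONTROL_LOCUS_LOCAL = (9_001, 10_200)

_ZYGOSITIES = ("wt", "hemizygous", "homozygous")


@dataclass(frozen=True)
class Contig:
    name: str
    chrom: str
    global_start: int
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class IntegrationScenario:
    """Planted integration: coordinates are global, 1-based, retained-flank
    convention (left_bp = last retained base, right_bp = first retained base)."""

    chrom: str = "chr12"
    left_bp: int = 78_137_441
    right_bp: int = 78_139_250
    copies: int = 15
    h_left: int = 4
    h_right: int = 5
    zygosity: str = "homozygous"
    orientation: str = "+"

    @property
    def deletion_length(self) -> int:
        return self.right_bp - self.left_bp - 1

    def __post_init__(self) -> None:
        if self.right_bp <= self.left_bp + 1:
            raise ValueError("right_bp must exceed left_bp + 1")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if self.h_left < 0 or self.h_right < 0:
            raise ValueError("microhomology lengths must be >= 0")
        if self.h_left + self.h_right >= self.deletion_length:
            raise ValueError("homology tracts must fit inside the deletion")
        if self.zygosity not in _ZYGOSITIES:
            raise ValueError(f"zygosity must be one of {_ZYGOSITIES}")
        if self.orientation not in ("+", "-"):
            raise ValueError("orientation must be '+' or '-'")


@dataclass
class ReferenceSet:
    """Named contigs with global-coordinate offsets plus locus annotations."""

    contigs: list[Contig]
    transgene_name: str = TRANSGENE_NAME
    arc_locus: tuple[str, int, int] = ("chr15", *ARC_LOCUS_GLOBAL)
    control_locus: tuple[str, int, int] = (
        CONTROL_CHROM,
        CONTROL_START + CONTROL_LOCUS_LOCAL[0] - 1,
        CONTROL_START + CONTROL_LOCUS_LOCAL[1] - 1,
    )
    # Intervals (local, 1-based inclusive) sharing the Arc cDNA sequence, per
    # contig; every cDNA position occurs once per interval set per copy.
    shared_cdna_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    cdna_len_per_copy: int = ARC_CDNA_LEN
    tg_layout: dict[str, tuple[int, int]] = field(default_factory=dict)

    def contig(self, name: str) -> Contig:
        for c in self.contigs:
            if c.name == name:
                return c
        raise KeyError(f"unknown contig {name!r}")

    def seq(self, name: str) -> str:
        return self.contig(name).sequence

    def local_to_global(self, name: str, pos: int) -> int:
        return self.contig(name).global_start + pos - 1

    def global_to_local(self, chrom: str, gpos: int) -> tuple[str, int]:
        for c in self.contigs:
            if c.chrom == chrom and c.global_start <= gpos < c.global_start + len(c):
                return c.name, gpos - c.global_start + 1
        raise ValueError(f"{chrom}:{gpos} outside modelled windows")

    @property
    def transgene_seq(self) -> str:
        return self.seq(self.transgene_name)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for c in self.contigs:
                fh.write(f">{c.name} chrom={c.chrom} global_start={c.global_start}\n")
                for i in range(0, len(c), 80):
                    fh.write(c.sequence[i:i + 80] + "\n")


def _oriented(tg: str, orientation: str) -> str:
    return tg if orientation == "+" else revcomp(tg)


def _extension_stop(ins: np.ndarray, chrom: np.ndarray, start: int, step: int,
                    ins_from_end: bool, n: int = 60) -> int:
    """How far a greedy ungapped aligner (match +1 / mismatch -4) extends the
    insert terminus along the chromosome; the best-scoring prefix length."""
    scores = []
    total = 0
    for i in range(n):
        ci = start + step * i
        if ci < 0 or ci >= len(chrom):
            break
        ib = ins[-1 - i] if ins_from_end else ins[i]
        total += 1 if ib == chrom[ci] else -4
        scores.append(total)
    if not scores:
        return 0
    best = int(np.argmax(scores))
    return best + 1 if scores[best] > 0 else 0


def build_reference_set(
    seed: int,
    scenario: IntegrationScenario | None = None,
    *,
    chr12_len: int = DEFAULT_CHR12_LEN,
    chr15_len: int = DEFAULT_CHR15_LEN,
    control_len: int = DEFAULT_CONTROL_LEN,
) -> ReferenceSet:
    """Draw the reference windows and assemble the transgene.

    Deterministic for a fixed seed.  Raises ``ValueError`` when the scenario's
    homology tracts would not fit in the chr12 window.
    """
    scenario = scenario or IntegrationScenario()
    rng = np.random.default_rng(seed)

    l0 = scenario.left_bp - CHR12_START + 1   # local 1-based
    r0 = scenario.right_bp - CHR12_START + 1
    if not (1 <= l0 < r0 <= chr12_len):
        raise ValueError("scenario breakpoints outside the chr12 window")
    if l0 + scenario.h_left + 1 >= chr12_len or r0 - scenario.h_right - 1 < 1:
        raise ValueError("homology tract exceeds flank length")
    if TG_UTR3_LEN <= 0:
        raise ValueError("transgene shorter than the sum of its fixed components")

    c12 = random_codes(rng, chr12_len)
    c15 = random_codes(rng, chr15_len)
    ctrl = random_codes(rng, control_len)

    gene_lo = CHR15_GENE_START - 1                       # 0-based
    gene_hi = gene_lo + ARC_CDNA_LEN
    if gene_hi > chr15_len:
        raise ValueError("chr15 window too short for the Arc gene body")
    utr5 = c15[gene_lo:gene_lo + TG_UTR5_LEN]
    orf = c15[gene_lo + TG_UTR5_LEN:gene_lo + TG_UTR5_LEN + TG_ORF_LEN]
    utr3 = c15[gene_lo + TG_UTR5_LEN + TG_ORF_LEN:gene_hi]

    promoter = random_codes(rng, TG_PROMOTER_LEN)
    egfp = random_codes(rng, TG_EGFP_LEN)
    tg = np.concatenate([promoter, utr5, egfp, orf, utr3])
    assert tg.size == TRANSGENE_LEN

    # The inserted unit in chromosome orientation.
    ins = tg if scenario.orientation == "+" else (3 - tg[::-1]).astype(np.uint8)
    hl, hr = scenario.h_left, scenario.h_right
    n = ins.size

    for _ in range(200):
        if hl:
            ins[:hl] = c12[l0:l0 + hl]
        if hr:
            ins[n - hr:] = c12[r0 - 1 - hr:r0 - 1]
        ins_s, c12_s = decode(ins), decode(c12)
        ok = (
            homology_after(ins_s, c12_s, l0) == hl
            and homology_at_left_clip(ins_s, c12_s, l0 + hl) == hl
            and homology_before(ins_s, c12_s, r0) == hr
            and homology_at_right_clip(ins_s, c12_s, r0 - hr) == hr
            and _extension_stop(ins, c12, l0, +1, ins_from_end=False) == hl
            and _extension_stop(ins, c12, r0 - 2, -1, ins_from_end=True) == hr
        )
        if ok:
            break
        # Resample free bases near the junctions: retained flank, deleted
        # bases beyond the homology tracts, and insert interior bases.
        c12[max(0, l0 - 6):l0] = random_codes(rng, min(6, l0))
        c12[l0 + hl:l0 + hl + 8] = random_codes(rng, min(8, chr12_len - l0 - hl))
        lo_del = max(0, r0 - 1 - hr - 8)
        c12[lo_del:r0 - 1 - hr] = random_codes(rng, r0 - 1 - hr - lo_del)
        c12[r0 - 1:r0 + 5] = random_codes(rng, min(6, chr12_len - r0 + 1))
        ins[hl:hl + 6] = random_codes(rng, 6)
        ins[n - hr - 6:n - hr] = random_codes(rng, 6)
    else:  # pragma: no cover - resampling converges in a few iterations
        raise RuntimeError("could not plant unambiguous junction homologies")

    tg = ins if scenario.orientation == "+" else (3 - ins[::-1]).astype(np.uint8)

    contigs = [
        Contig("chr12", "chr12", CHR12_START, decode(c12)),
        Contig("chr15", "chr15", CHR15_START, decode(c15)),
        Contig(CONTROL_CHROM, CONTROL_CHROM, CONTROL_START, decode(ctrl)),
        Contig(TRANSGENE_NAME, TRANSGENE_NAME, 1, decode(tg)),
    ]
    tg_layout = {
        "promoter": (1, TG_PROMOTER_LEN),
        "utr5": (TG_PROMOTER_LEN + 1, TG_PROMOTER_LEN + TG_UTR5_LEN),
        "egfp": (TG_PROMOTER_LEN + TG_UTR5_LEN + 1,
                 TG_PROMOTER_LEN + TG_UTR5_LEN + TG_EGFP_LEN),
        "orf": (TG_PROMOTER_LEN + TG_UTR5_LEN + TG_EGFP_LEN + 1,
                TG_PROMOTER_LEN + TG_UTR5_LEN + TG_EGFP_LEN + TG_ORF_LEN),
        "utr3": (TG_PROMOTER_LEN + TG_UTR5_LEN + TG_EGFP_LEN + TG_ORF_LEN + 1,
                 TRANSGENE_LEN),
    }
    shared = {
        TRANSGENE_NAME: [tg_layout["utr5"], (tg_layout["orf"][0], tg_layout["utr3"][1])],
        "chr15": [(CHR15_GENE_START, CHR15_GENE_START + ARC_CDNA_LEN - 1)],
    }
    return ReferenceSet(contigs=contigs, shared_cdna_intervals=shared, tg_layout=tg_layout)


def build_transgenic_allele(refs: ReferenceSet, scenario: IntegrationScenario) -> str:
    """The chr12 haplotype implied by the scenario: left flank + C tandem
    oriented transgene copies + right flank (wt zygosity: the window itself)."""
    c12 = refs.seq("chr12")
    if scenario.zygosity == "wt":
        return c12
    name, l0 = refs.global_to_local(scenario.chrom, scenario.left_bp)
    _, r0 = refs.global_to_local(scenario.chrom, scenario.right_bp)
    if name != "chr12":
        raise ValueError("scenario chromosome not modelled by these references")
    ins = _oriented(refs.transgene_seq, scenario.orientation)
    if scenario.h_left and homology_after(ins, c12, l0) != scenario.h_left:
        raise ValueError("scenario/references mismatch: planted homology absent")
    return c12[:l0] + ins * scenario.copies + c12[r0 - 1:]


def diploid_haplotypes(
    refs: ReferenceSet, scenario: IntegrationScenario
) -> list[tuple[str, str]]:
    """The six sequenced haplotypes: two chr12 alleles per zygosity plus both
    copies of the chr15 and control windows."""
    wt = refs.seq("chr12")
    tg_allele = build_transgenic_allele(refs, scenario)
    alleles = {
        "wt": [wt, wt],
        "hemizygous": [tg_allele, wt],
        "homozygous": [tg_allele, tg_allele],
    }[scenario.zygosity]
    haps = [(f"chr12_hap{i + 1}", s) for i, s in enumerate(alleles)]
    for w in ("chr15", CONTROL_CHROM):
        haps += [(f"{w}_hap{i + 1}", refs.seq(w)) for i in range(2)]
    return haps
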