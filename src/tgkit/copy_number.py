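"""Transgene copy number per locus from read depth and from qPCR Ct tables.

Both estimators express Arc-ORF dosage relative to a 2-copy control gene
and convert total ORF copies per diploid genome into copies per transgenic
locus via ``per_locus = (total - 2) / n_loci`` with n_loci = 1 (hemizygous)
or 2 (homozygous); the "- 2" removes the endogenous alleles.

Read depth: the transgene shares the Arc cDNA (5'UTR + ORF + 3'UTR,
4,079 bp per copy) with the endogenous locus, so reads from any copy land
somewhere in the shared intervals — multi-mapping (mapq 0) hits included,
otherwise the estimate deflates.  Summing M-bases over ALL shared intervals
and dividing by the per-copy shared length gives the total copy-depth,
which is normalized by the mean depth of the single-copy control window:

    total_copies = 2 * (sum of M-bases in shared intervals / L_per_copy)
                     / mean control depth

qPCR: relative quantity = E^(ddCt) with dCt = Ct(control) - Ct(ORF) and
ddCt = dCt(sample) - mean dCt(calibrator WT samples); total = 2 * relative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage import depth_array
from .mapper import AlignmentRecord
from .synthgen.genome import ReferenceSet
from .synthgen.qpcr import CONTROL_TARGET, ORF_TARGET


@dataclass
class CopyNumberEstimate:
    total_copies: float          # Arc-ORF copies per diploid genome
    per_locus: float             # transgene copies per transgenic locus
    per_locus_rounded: int
    method: str                  # 'depth' | 'qpcr'
    n_loci: int
    dispersion: float | None = None


def n_transgenic_loci(zygosity: str) -> int:
    return {"wt": 0, "hemizygous": 1, "heterozygous": 1, "homozygous": 2}[zygosity]


def _per_locus(total: float, n_loci: int) -> float:
    return (total - 2.0) / n_loci if n_loci else 0.0


def depth_copy_number(
    records: Sequence[AlignmentRecord],
    refs: ReferenceSet,
    zygosity: str,
    control_interval: tuple[str, int, int] | None = None,
) -> CopyNumberEstimate:
    """Estimate copies from M-base depth (mapq-0 alignments included).

    ``control_interval`` defaults to the interior of the single-copy control
    window (500-bp edges excluded to avoid contig-end depth falloff).
    """
    records = [r for r in records if r.is_mapped]
    if control_interval is None:
        chrom = refs.control_locus[0]
        c = refs.contig(chrom)
        control_interval = (c.name, 501, len(c) - 500)
    cname, clo, chi = control_interval
    ctrl_depth = depth_array(records, cname, clo, chi)
    ctrl_mean = float(ctrl_depth.mean())
    if ctrl_mean == 0:
        raise ValueError("zero depth over the control interval")

    total_bases = 0.0
    family_means = []
    for contig, intervals in refs.shared_cdna_intervals.items():
        for lo, hi in intervals:
            d = depth_array(records, contig, lo, hi)
            total_bases += float(d.sum())
            family_means.append(float(d.mean()))
    copy_depth = total_bases / refs.cdna_len_per_copy
    total = 2.0 * copy_depth / ctrl_mean
    n_loci = n_transgenic_loci(zygosity)
    per_locus = _per_locus(total, n_loci)
    return CopyNumberEstimate(
        total_copies=total,
        per_locus=per_locus,
        per_locus_rounded=int(round(per_locus)),
        method="depth",
        n_loci=n_loci,
        dispersion=float(np.std(family_means)) if len(family_means) > 1 else None,
    )


def qpcr_copy_number(
    table: pd.DataFrame,
    sample: str,
    zygosity: str,
    calibrator: Sequence[str],
    efficiency: float = 2.0,
) -> CopyNumberEstimate:
    """ddCt relative quantification of one sample against WT calibrators.

    The table needs columns (sample, target, replicate, ct) with both
    targets present for the sample and every calibrator.
    """
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must be > 1")
    if not calibrator:
        raise ValueError("need at least one calibrator sample")

    def _dct(name: str) -> float:
        sub = table[table["sample"] == name]
        cts = {t: sub[sub["target"] == t]["ct"] for t in (ORF_TARGET, CONTROL_TARGET)}
        if any(len(v) == 0 for v in cts.values()):
            raise ValueError(f"sample {name!r} missing a target")
        return float(cts[CONTROL_TARGET].mean() - cts[ORF_TARGET].mean())

    cal_dct = float(np.mean([_dct(c) for c in calibrator]))
    ddct = _dct(sample) - cal_dct
    total = 2.0 * efficiency**ddct
    n_loci = n_transgenic_loci(zygosity)
    per_locus = _per_locus(total, n_loci)

    # Replicate-level dispersion: pair replicates by index within the sample.
    sub = table[table["sample"] == sample]
    orf = sub[sub["target"] == ORF_TARGET].sort_values("replicate")["ct"].to_numpy()
    ctl = sub[sub["target"] == CONTROL_TARGET].sort_values("replicate")["ct"].to_numpy()
    disp = None
    if orf.size == ctl.size and orf.size > 1:
        rep_tot = 2.0 * efficiency ** ((ctl - orf) - cal_dct)
        disp = float(np.std([_per_locus(t, n_loci) for t in rep_tot])) if n_loci else 0.0

    return CopyNumberEstimate(
        total_copies=total,
        per_locus=per_locus,
        per_locus_rounded=int(round(per_locus)),
        method="qpcr",
        n_loci=n_loci,
        dispersion=disp,
    )
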