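"""SYBR qPCR plate simulator for Arc-ORF copy number, normalized to gapdh.

The cycle threshold follows the exponential amplification model
``Ct = baseline - log_E(copies / 2) + noise`` with amplification efficiency
E per cycle (E = 2 is perfect doubling).  The calibrator state is the WT
diploid (2 ORF copies, 2 control copies), so a WT sample has equal Cts for
both targets.  Arc-ORF copy number per diploid genome is 2 (wt), 2 + C
(hemizygous) or 2 + 2C (homozygous) for C transgene copies per locus; the
control gene is always 2 copies.

Defaults model the study's genotyping cohort: 16 animals (5 WT, 5
hemizygous, 6 homozygous) with 3 technical replicates and 0.03-cycle
replicate scatter, a well-optimized assay on purified genomic DNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ORF_TARGET = "ArcORF"
CONTROL_TARGET = "gapdh"


def orf_copies(zygosity: str, copies_per_locus: int) -> int:
    return {
        "wt": 2,
        "hemizygous": 2 + copies_per_locus,
        "homozygous": 2 + 2 * copies_per_locus,
    }[zygosity]


@dataclass
class QpcrPlateSpec:
    efficiency: float = 2.0
    baseline_ct: float = 24.0
    replicates: int = 3
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError("efficiency must be in (1, 2]")
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")


def default_panel(copies_per_locus: int = 15) -> dict[str, tuple[str, int]]:
    """sample name -> (zygosity, copies per locus); the 16-animal cohort."""
    panel: dict[str, tuple[str, int]] = {}
    for i in range(5):
        panel[f"wt_{i + 1}"] = ("wt", 0)
    for i in range(5):
        panel[f"hemi_{i + 1}"] = ("hemizygous", copies_per_locus)
    for i in range(6):
        panel[f"homo_{i + 1}"] = ("homozygous", copies_per_locus)
    return panel


def simulate_qpcr_plate(
    spec: QpcrPlateSpec | None = None,
    panel: dict[str, tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Ct table with columns (sample, target, replicate, ct)."""
    spec = spec or QpcrPlateSpec()
    panel = panel if panel is not None else default_panel()
    rng = np.random.default_rng(spec.seed)
    log_e = np.log(spec.efficiency)
    rows = []
    for sample, (zyg, c) in panel.items():
        for target, copies in ((ORF_TARGET, orf_copies(zyg, c)), (CONTROL_TARGET, 2)):
            ct0 = spec.baseline_ct - np.log(copies / 2.0) / log_e
            for rep in range(1, spec.replicates + 1):
                rows.append((sample, target, rep, ct0 + rng.normal(0.0, spec.noise_sd)))
    return pd.DataFrame(rows, columns=["sample", "target", "replicate", "ct"])
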