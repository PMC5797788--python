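"""End-to-end scenario runner, report bundle, and small derived quantities.

``run_default_scenario`` executes the whole genomics arm on synthetic data with a
known ground truth: build references and the transgenic diploid, simulate
the 13.5x paired-end library, trim and filter, map, call the integration
site, and estimate copy number by read depth and by simulated qPCR.  All
randomness fans out from one top-level seed, so a bundle is reproducible
from (config, seed) alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np

from .copy_number import CopyNumberEstimate, depth_copy_number, qpcr_copy_number
from .integration_caller import CallerConfig, IntegrationCall, call_integration
from .mapper import MapParams, build_index, map_pairs
from .readprep import PairFilterParams, trim_and_filter
from .synthgen.genome import (
    IntegrationScenario,
    ReferenceSet,
    build_reference_set,
    diploid_haplotypes,
)
from .synthgen.qpcr import QpcrPlateSpec, default_panel, simulate_qpcr_plate
from .synthgen.reads import ReadSimParams, simulate_read_pairs


@dataclass
class ScenarioConfig:
    """Named bundle of generator + pipeline parameters.

    The defaults encode the printed integration: breakpoints
    Chr12:78,137,441 / 78,139,250 (1,808-bp deletion), 4/5-bp junction
    microhomologies, 15 tandem copies, homozygous, 150-bp pairs at 13.5x.
    ``read_params.coverage`` is diploid genome coverage; the simulator is
    invoked with half of it per haplotype copy.
    """

    scenario: IntegrationScenario = field(default_factory=IntegrationScenario)
    read_params: ReadSimParams = field(default_factory=ReadSimParams)
    filter_params: PairFilterParams = field(default_factory=PairFilterParams)
    map_params: MapParams = field(default_factory=MapParams)
    caller: CallerConfig = field(default_factory=CallerConfig)
    qpcr: QpcrPlateSpec = field(default_factory=QpcrPlateSpec)

    @classmethod
    def default_scenario(cls, **overrides: Any) -> "ScenarioConfig":
        return cls(**overrides)

    def digest(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            return o

        blob = json.dumps(enc(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunArtifacts:
    refs: ReferenceSet
    records: list
    truth: Any
    plate: Any


@dataclass
class ReportBundle:
    call: IntegrationCall | None
    copy_depth: CopyNumberEstimate | None
    copy_qpcr: CopyNumberEstimate | None
    seed: int
    config_digest: str
    n_pairs_simulated: int
    n_pairs_kept: int
    artifacts: RunArtifacts | None = None

    def to_dict(self) -> dict:
        def est(e):
            return None if e is None else {
                "total_copies": e.total_copies,
                "per_locus": e.per_locus,
                "per_locus_rounded": e.per_locus_rounded,
                "method": e.method,
                "n_loci": e.n_loci,
                "dispersion": e.dispersion,
            }

        return {
            "integration_call": None if self.call is None else self.call.to_dict(),
            "copy_number": {"depth": est(self.copy_depth), "qpcr": est(self.copy_qpcr)},
            "provenance": {
                "seed": self.seed,
                "config_digest": self.config_digest,
                "n_pairs_simulated": self.n_pairs_simulated,
                "n_pairs_kept": self.n_pairs_kept,
            },
        }


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(ss.generate_state(1)[0] % 2**31)
            for ss in np.random.SeedSequence(seed).spawn(n)]


def run_default_scenario(
    config: ScenarioConfig | None = None,
    seed: int = 1,
    keep_artifacts: bool = False,
) -> ReportBundle:
    """Simulate the default scenario and recover it; see module docstring."""
    config = config or ScenarioConfig.default_scenario()
    s_ref, s_reads, s_qpcr = _child_seeds(seed, 3)

    refs = build_reference_set(s_ref, config.scenario)
    haps = diploid_haplotypes(refs, config.scenario)
    sim_params = replace(
        config.read_params, coverage=config.read_params.coverage / 2.0, seed=s_reads
    )
    reads1, reads2, truth = simulate_read_pairs(haps, sim_params)
    pairs, filt = trim_and_filter(reads1, reads2, config.filter_params)
    index = build_index(refs, config.map_params.k)
    records = map_pairs(pairs, index, config.map_params)

    call = call_integration(records, refs, config.caller)
    zygosity = call.zygosity if call is not None else "wt"

    copy_depth = depth_copy_number(records, refs, zygosity)

    plate_spec = replace(config.qpcr, seed=s_qpcr)
    panel = default_panel(config.scenario.copies)
    plate = simulate_qpcr_plate(plate_spec, panel)
    sample = {
        "wt": "wt_1", "hemizygous": "hemi_1", "homozygous": "homo_1",
    }[config.scenario.zygosity]
    calibrators = [s for s in panel if s.startswith("wt_")]
    copy_qpcr = qpcr_copy_number(
        plate, sample, zygosity, calibrators, plate_spec.efficiency
    )

    return ReportBundle(
        call=call,
        copy_depth=copy_depth,
        copy_qpcr=copy_qpcr,
        seed=seed,
        config_digest=config.digest(),
        n_pairs_simulated=filt.pairs_in,
        n_pairs_kept=filt.pairs_kept,
        artifacts=RunArtifacts(refs, records, truth, plate) if keep_artifacts else None,
    )


def fusion_protein_mass(component_masses_kda: list[float] | tuple[float, ...]) -> float:
    """Predicted fusion-protein mass: the sum of its components' masses (kDa)."""
    if not component_masses_kda:
        raise ValueError("need at least one component mass")
    if any(m <= 0 for m in component_masses_kda):
        raise ValueError("component masses must be positive")
    return float(sum(component_masses_kda))


def write_reports(bundle: ReportBundle, outdir: str | Path) -> list[Path]:
    """Write the bundle as JSON + TSV reports plus a provenance log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    report = outdir / "report.json"
    report.write_text(json.dumps(bundle.to_dict(), indent=2) + "\n")
    written.append(report)

    call_tsv = outdir / "integration_call.tsv"
    d = bundle.call.to_dict() if bundle.call is not None else {}
    cols = ["chrom", "left_bp", "right_bp", "deletion_length", "h_left",
            "h_right", "orientation", "support_left", "support_right",
            "zygosity", "low_confidence"]
    call_tsv.write_text(
        "\t".join(cols) + "\n"
        + "\t".join("NA" if d.get(c) is None else str(d.get(c)) for c in cols) + "\n"
    )
    written.append(call_tsv)

    cn_tsv = outdir / "copy_number.tsv"
    lines = ["method\ttotal_copies\tper_locus\tper_locus_rounded"]
    for est in (bundle.copy_depth, bundle.copy_qpcr):
        if est is None:
            lines.append("NA\tNA\tNA\tNA")
        else:
            lines.append(
                f"{est.method}\t{est.total_copies:.4f}\t{est.per_locus:.4f}"
                f"\t{est.per_locus_rounded}"
            )
    cn_tsv.write_text("\n".join(lines) + "\n")
    written.append(cn_tsv)

    log = outdir / "run.log"
    log.write_text(
        f"seed={bundle.seed}\nconfig_digest={bundle.config_digest}\n"
        f"pairs_simulated={bundle.n_pairs_simulated}\n"
        f"pairs_kept={bundle.n_pairs_kept}\n"
    )
    written.append(log)
    return written
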