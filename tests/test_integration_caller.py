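"""Integration-site recovery: extraction, region, gap, breakpoints, scans, PCR."""

import numpy as np
import pytest

from tgkit.dna import revcomp
from tgkit.integration_caller import (
    CallerConfig,
    CandidateRegion,
    call_integration,
    detect_coverage_gap,
    extract_informative_pairs,
    insilico_pcr,
    locate_candidate_region,
    resolve_breakpoints,
    scan_secondary_integrations,
)
from tgkit.mapper import AlignmentRecord, build_index, map_pairs
from tgkit.readprep import trim_and_filter
from tgkit.synthgen.genome import (
    CONTROL_CHROM,
    IntegrationScenario,
    build_reference_set,
    build_transgenic_allele,
    diploid_haplotypes,
)
from tgkit.synthgen.reads import ReadSimParams, simulate_read_pairs

PLANTED_LEFT = 78_137_441
PLANTED_RIGHT = 78_139_250


def _rec(qname, mate, contig, pos, mlen=150, **kw):
    return AlignmentRecord(qname, mate, contig, pos=pos, mlen=mlen,
                           seq="A" * mlen, **kw)


class TestExtraction:
    def test_membership_criterion(self, refs_default):
        tg = refs_default.transgene_name
        arc_lo = refs_default.arc_locus[1] - refs_default.contig("chr15").global_start + 1
        records = [
            _rec("tg_pair", 1, tg, 100), _rec("tg_pair", 2, "chr12", 500),
            _rec("ctrl_pair", 1, CONTROL_CHROM, 100), _rec("ctrl_pair", 2, CONTROL_CHROM, 400),
            _rec("arc_pair", 1, "chr15", arc_lo + 10), _rec("arc_pair", 2, "chr15", arc_lo - 4000),
        ]
        pairs = extract_informative_pairs(records, refs_default)
        names = {p[0].qname for p in pairs.pairs}
        assert names == {"tg_pair", "arc_pair"}

    def test_unknown_transgene_name_rejected(self, refs_default):
        from dataclasses import replace

        bad = replace(refs_default, transgene_name="nonexistent")
        with pytest.raises(ValueError):
            extract_informative_pairs([], bad)


class TestCandidateRegion:
    def test_default_scenario_region_contains_the_locus(self, default_bundle):
        call = default_bundle.call
        region = call.region
        assert region.chrom == "chr12"
        assert region.start <= 78_138_000 <= region.end
        assert region.end - region.start + 1 == 8_000

    def test_wt_input_gives_no_candidate(self, wt_bundle):
        refs = wt_bundle.artifacts.refs
        pairs = extract_informative_pairs(wt_bundle.artifacts.records, refs)
        assert locate_candidate_region(pairs, refs) is None
        assert wt_bundle.call is None


class TestCoverageGap:
    def test_homozygous_gap_spans_deletion_minus_homology(self, default_bundle):
        gap = default_bundle.call.gap
        assert gap.mode == "homozygous"
        # junction reads cover the homology bases, so the zero-depth run is
        # about deletion - h_left - h_right = 1,799 bp (short unextendable
        # tails absorbed into M can nibble a few bases off either edge)
        assert 1_770 <= gap.length <= 1_799
        assert gap.start >= PLANTED_LEFT + 1 and gap.end <= PLANTED_RIGHT - 1

    def test_wt_reads_show_no_gap(self, wt_bundle):
        refs = wt_bundle.artifacts.refs
        contig = refs.contig("chr12")
        region = CandidateRegion(
            chrom="chr12", start=78_134_001, end=78_142_000, contig="chr12",
            start_local=78_134_001 - contig.global_start + 1,
            end_local=78_142_000 - contig.global_start + 1,
        )
        gap = detect_coverage_gap(wt_bundle.artifacts.records, region, refs)
        assert gap is None

    def test_hemizygous_depth_drop_overlaps_deletion(self, hemi_bundle):
        refs = hemi_bundle.artifacts.refs
        contig = refs.contig("chr12")
        region = CandidateRegion(
            chrom="chr12", start=78_134_001, end=78_142_000, contig="chr12",
            start_local=78_134_001 - contig.global_start + 1,
            end_local=78_142_000 - contig.global_start + 1,
        )
        records = hemi_bundle.artifacts.records
        assert detect_coverage_gap(records, region, refs, mode="homozygous") is None
        gap = detect_coverage_gap(records, region, refs, mode="depth_drop")
        assert gap is not None
        assert gap.start < PLANTED_RIGHT and gap.end > PLANTED_LEFT


class TestBreakpoints:
    def test_default_scenario_recovers_printed_coordinates(self, default_bundle):
        call = default_bundle.call
        assert (call.left_bp, call.right_bp) == (PLANTED_LEFT, PLANTED_RIGHT)
        assert (call.h_left, call.h_right) == (4, 5)
        assert call.deletion_length == 1_808
        assert call.orientation == "+"
        assert call.zygosity == "homozygous"
        assert not call.low_confidence

    def test_zero_homology_breakpoints_equal_clip_consensus(self):
        sc = IntegrationScenario(h_left=0, h_right=0)
        from tgkit.pipeline import ScenarioConfig, run_default_scenario

        bundle = run_default_scenario(ScenarioConfig.default_scenario(scenario=sc), seed=1)
        call = bundle.call
        assert (call.left_bp, call.right_bp) == (PLANTED_LEFT, PLANTED_RIGHT)
        assert (call.h_left, call.h_right) == (0, 0)

    def test_low_confidence_contract_at_minimal_coverage(self, refs_default):
        sc = IntegrationScenario()
        haps = diploid_haplotypes(refs_default, sc)
        params = ReadSimParams(coverage=1.0, seed=1)   # 2x over the diploid
        r1, r2, _ = simulate_read_pairs(haps, params)
        pairs, _ = trim_and_filter(r1, r2)
        records = map_pairs(pairs, build_index(refs_default))
        contig = refs_default.contig("chr12")
        region = CandidateRegion(
            chrom="chr12", start=78_134_001, end=78_142_000, contig="chr12",
            start_local=78_134_001 - contig.global_start + 1,
            end_local=78_142_000 - contig.global_start + 1,
        )
        gap = detect_coverage_gap(records, region, refs_default)
        assert gap is not None
        bp = resolve_breakpoints(records, gap, refs_default)
        cfg = CallerConfig()
        assert bp.low_confidence == (
            bp.support_left < cfg.min_support or bp.support_right < cfg.min_support
        )

    def test_convention_consistency_on_evidence(self, default_bundle):
        """left_bp + h_left and right_bp - h_right equal the clip consensus."""
        refs = default_bundle.artifacts.refs
        call = default_bundle.call
        gap = call.gap
        bp = resolve_breakpoints(default_bundle.artifacts.records, gap, refs)
        left_clips = [e.clip_pos_local for e in bp.evidence
                      if e.side == "left" and e.source == "flank"]
        right_clips = [e.clip_pos_local for e in bp.evidence
                       if e.side == "right" and e.source == "flank"]
        l_local = bp.left_bp_local
        r_local = bp.right_bp_local
        assert max(set(left_clips), key=left_clips.count) == l_local + bp.h_left
        assert max(set(right_clips), key=right_clips.count) == r_local - bp.h_right


class TestOrchestration:
    def test_wt_scenario_yields_clean_no_call(self, wt_bundle):
        assert wt_bundle.call is None
        assert wt_bundle.copy_depth.per_locus == 0.0

    def test_deletion_length_formula(self, default_bundle):
        call = default_bundle.call
        assert call.deletion_length == call.right_bp - call.left_bp - 1
        from dataclasses import replace

        toy = replace(call, left_bp=100, right_bp=102)
        assert toy.deletion_length == 1


class TestSecondaryScan:
    def test_default_scenario_has_no_secondary_sites(self, default_bundle):
        assert default_bundle.call.secondary_sites == []

    def test_wt_scan_is_empty(self, wt_bundle):
        refs = wt_bundle.artifacts.refs
        assert scan_secondary_integrations(
            wt_bundle.artifacts.records, refs, [("chr12", PLANTED_LEFT)]
        ) == []

    def test_spiked_second_insertion_is_detected(self, refs_default):
        sc = IntegrationScenario()
        tg = refs_default.transgene_seq
        ctrl = refs_default.seq(CONTROL_CHROM)
        spiked = ctrl[:60_000] + tg + ctrl[60_000:]
        haps = [
            ("chr12_a", build_transgenic_allele(refs_default, sc)),
            ("chr12_b", build_transgenic_allele(refs_default, sc)),
            ("chr15_a", refs_default.seq("chr15")),
            ("ctrl_spiked", spiked),
            ("ctrl_wt", ctrl),
        ]
        r1, r2, _ = simulate_read_pairs(haps, ReadSimParams(coverage=6.75, seed=6))
        pairs, _ = trim_and_filter(r1, r2)
        records = map_pairs(pairs, build_index(refs_default))
        sites = scan_secondary_integrations(
            records, refs_default, [("chr12", PLANTED_LEFT)]
        )
        assert len(sites) == 1
        assert sites[0].chrom == CONTROL_CHROM
        expected = refs_default.contig(CONTROL_CHROM).global_start + 60_000
        assert abs(sites[0].position - expected) < 2_000


class TestInsilicoPcr:
    def test_junction_and_wt_primer_sets(self, refs_default):
        sc = IntegrationScenario()
        allele = build_transgenic_allele(refs_default, sc)
        wt = refs_default.seq("chr12")
        l0 = PLANTED_LEFT - refs_default.contig("chr12").global_start + 1
        fwd = wt[l0 - 220: l0 - 190]                       # left flank
        rev_junction = revcomp(allele[l0 + 120: l0 + 150])  # inside the transgene
        assert insilico_pcr(allele, fwd, rev_junction) == [370]
        assert insilico_pcr(wt, fwd, rev_junction) == []
        rev_wt = revcomp(wt[l0 + 500: l0 + 530])            # inside the deletion
        assert insilico_pcr(wt, fwd, rev_wt) == [750]
        assert insilico_pcr(allele, fwd, rev_wt) == []

    def test_no_match_gives_empty_list(self):
        assert insilico_pcr("ACGT" * 100, "TTTTTTTTTTTT", "GGGGGGGGGGGG") == []

    def test_empty_primer_rejected(self):
        with pytest.raises(ValueError):
            insilico_pcr("ACGT", "", "ACG")

    def test_max_len_bounds_products(self, refs_default):
        wt = refs_default.seq("chr12")
        fwd = wt[1_000:1_030]
        rev = revcomp(wt[9_000:9_030])
        assert insilico_pcr(wt, fwd, rev, max_len=5_000) == []
        assert insilico_pcr(wt, fwd, rev, max_len=10_000) == [8_030]
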