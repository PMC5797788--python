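"""Generator ground truth: references, alleles, reads, plates, stacks, series."""

import math
from dataclasses import replace

import numpy as np
import pytest

from tgkit.decay_kinetics import fit_half_life
from tgkit.microhomology import homology_after, homology_before
from tgkit.synthgen.decay import DecaySeriesSpec, simulate_decay_series
from tgkit.synthgen.genome import (
    TRANSGENE_LEN,
    IntegrationScenario,
    build_reference_set,
    build_transgenic_allele,
    diploid_haplotypes,
)
from tgkit.synthgen.imaging import BandSpec, FishImageSpec, render_fish_stack
from tgkit.synthgen.qpcr import QpcrPlateSpec, default_panel, simulate_qpcr_plate
from tgkit.synthgen.reads import ReadSimParams, simulate_read_pairs


class TestReferenceSet:
    def test_transgene_length_is_11829(self, refs_default):
        assert len(refs_default.transgene_seq) == TRANSGENE_LEN == 11_829

    def test_planted_microhomologies_verifiable_by_string_comparison(self, refs_default):
        sc = IntegrationScenario()
        c12 = refs_default.seq("chr12")
        tg = refs_default.transgene_seq
        l0 = sc.left_bp - refs_default.contig("chr12").global_start + 1
        r0 = sc.right_bp - refs_default.contig("chr12").global_start + 1
        # First h_left inserted bases repeat the first deleted chr12 bases.
        assert tg[: sc.h_left] == c12[l0: l0 + sc.h_left]
        # Last h_right inserted bases repeat the last deleted chr12 bases.
        assert tg[-sc.h_right:] == c12[r0 - 1 - sc.h_right: r0 - 1]
        # And the shared tracts are maximal (exactly h, not more).
        assert homology_after(tg, c12, l0) == sc.h_left
        assert homology_before(tg, c12, r0) == sc.h_right

    def test_disabled_homology_means_no_forced_prefix(self):
        sc = IntegrationScenario(h_left=0)
        refs = build_reference_set(7, sc)
        c12 = refs.seq("chr12")
        l0 = sc.left_bp - refs.contig("chr12").global_start + 1
        assert homology_after(refs.transgene_seq, c12, l0) == 0

    def test_same_seed_is_byte_identical(self):
        a = build_reference_set(42)
        b = build_reference_set(42)
        assert all(x.sequence == y.sequence for x, y in zip(a.contigs, b.contigs))

    def test_chr15_window_contains_the_transgene_orf(self, refs_default):
        orf_lo, orf_hi = refs_default.tg_layout["orf"]
        tg = refs_default.transgene_seq
        assert tg[orf_lo - 1: orf_hi] in refs_default.seq("chr15")
        # the 5'UTR marker is shared as well
        u5_lo, u5_hi = refs_default.tg_layout["utr5"]
        assert tg[u5_lo - 1: u5_hi] in refs_default.seq("chr15")

    def test_scenario_validation(self):
        with pytest.raises(ValueError):
            IntegrationScenario(left_bp=10, right_bp=10)
        with pytest.raises(ValueError):
            IntegrationScenario(copies=0)
        with pytest.raises(ValueError):
            build_reference_set(1, IntegrationScenario(left_bp=78_100_001,
                                                       right_bp=78_100_003,
                                                       h_left=1, h_right=0))


class TestTransgenicAllele:
    @pytest.mark.parametrize("copies,expected", [(15, 255_627), (1, 90_021)])
    def test_allele_length_identity(self, refs_default, copies, expected):
        sc = IntegrationScenario(copies=copies)
        allele = build_transgenic_allele(refs_default, sc)
        assert len(allele) == expected
        assert len(allele) == 80_000 - sc.deletion_length + copies * TRANSGENE_LEN

    def test_wt_allele_is_the_window(self, refs_default):
        sc = IntegrationScenario(zygosity="wt")
        assert build_transgenic_allele(refs_default, sc) == refs_default.seq("chr12")

    def test_zygosity_controls_haplotype_mixture(self, refs_default):
        hemi = diploid_haplotypes(refs_default, IntegrationScenario(zygosity="hemizygous"))
        lens = sorted(len(s) for n, s in hemi if n.startswith("chr12"))
        assert lens == [80_000, 255_627]


class TestReadSimulation:
    def test_error_free_reads_are_exact_substrings(self):
        hap = build_reference_set(3).seq("chr15")
        params = ReadSimParams(coverage=2.0, error_scale=0.0, seed=5)
        r1, r2, truth = simulate_read_pairs([("h", hap)], params)
        from tgkit.dna import revcomp

        for a, b, (_, row) in zip(r1[:200], r2[:200], truth.iterrows()):
            frag = hap[row.frag_start - 1: row.frag_start - 1 + row.frag_len]
            assert a.seq == frag[:150]
            assert b.seq == revcomp(frag)[:150]

    def test_pair_count_matches_coverage_expectation(self):
        hap = build_reference_set(3).seq(
            "chr6"
        )
        params = ReadSimParams(coverage=13.5, seed=2)
        r1, _, _ = simulate_read_pairs([("h", hap)], params)
        expected = 13.5 * len(hap) / (2 * 150)
        assert abs(len(r1) - expected) / expected < 0.05

    def test_short_fragments_read_through_into_adapter(self):
        hap = build_reference_set(3).seq("chr15")
        params = ReadSimParams(
            insert_mean=120, insert_sd=0, coverage=1.0, error_scale=0.0, seed=1
        )
        r1, r2, truth = simulate_read_pairs([("h", hap)], params)
        assert (truth.frag_len == 120).all()
        for rec in (*r1[:50], *r2[:50]):
            assert rec.seq[120:120 + 30] == params.adapter[:30]

    def test_insert_statistics_within_3_sd(self):
        hap = build_reference_set(3).seq("chr6") * 2   # 300 kb -> ~10k fragments
        params = ReadSimParams(coverage=20.0, seed=9)
        _, _, truth = simulate_read_pairs([("h", hap)], params)
        n = len(truth)
        assert n > 10_000
        assert abs(truth.frag_len.mean() - 350) < 3 * 50 / math.sqrt(n)
        assert abs(truth.frag_len.std() - 50) < 3.0

    def test_same_seed_identical_reads(self):
        hap = build_reference_set(3).seq("chr15")
        params = ReadSimParams(coverage=1.0, seed=8)
        a = simulate_read_pairs([("h", hap)], params)
        b = simulate_read_pairs([("h", hap)], params)
        assert [r.seq for r in a[0]] == [r.seq for r in b[0]]
        assert all((x.qual == y.qual).all() for x, y in zip(a[1], b[1]))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ReadSimParams(coverage=0)
        with pytest.raises(ValueError):
            simulate_read_pairs([], ReadSimParams())


class TestQpcrPlate:
    def test_wt_sample_has_equal_cts(self):
        plate = simulate_qpcr_plate(QpcrPlateSpec(noise_sd=0.0), {"w": ("wt", 0)})
        by_target = plate.groupby("target")["ct"].mean()
        assert by_target["ArcORF"] == pytest.approx(by_target["gapdh"])

    def test_homozygous_delta_ct_is_log2_of_dosage(self):
        plate = simulate_qpcr_plate(
            QpcrPlateSpec(noise_sd=0.0), {"s": ("homozygous", 15)}
        )
        by_target = plate.groupby("target")["ct"].mean()
        assert by_target["gapdh"] - by_target["ArcORF"] == pytest.approx(
            math.log2(32 / 2)
        )

    def test_noiseless_replicates_identical(self):
        plate = simulate_qpcr_plate(QpcrPlateSpec(noise_sd=0.0, replicates=3))
        assert (plate.groupby(["sample", "target"])["ct"].nunique() == 1).all()

    def test_efficiency_must_exceed_one(self):
        with pytest.raises(ValueError):
            QpcrPlateSpec(efficiency=1.0)


class TestFishRendering:
    def test_zero_density_gives_background_only(self):
        spec = FishImageSpec.puncta_field(density=0.0, seed=1)
        stack, truth = render_fish_stack(spec)
        assert len(truth.puncta) == 0
        assert stack.data.shape == (4, 1024, 1024)

    def test_explicit_positions_are_echoed_in_truth(self):
        pts = [(float(10 + 2 * i), float(20 + i % 90), 0.8) for i in range(100)]
        spec = FishImageSpec.puncta_field(seed=1, puncta_positions=pts)
        _, truth = render_fish_stack(spec)
        assert len(truth.puncta) == 100

    def test_planted_fraction_exact_without_noise(self):
        spec = FishImageSpec.actd_field(
            seed=1, shot_noise=False, read_noise_sd=0.0,
            bands=(BandSpec("dentate", 819.2, 0.0, 120.0),),
        )
        stack, truth = render_fish_stack(spec)
        from tgkit.fish_quant import RegionSpec, max_project, region_remaining_fraction

        img = max_project(stack)
        pct = region_remaining_fraction(
            img, RegionSpec(center_px=(img.shape[1] / 2, img.shape[0] / 2)),
            stack.um_per_px,
        )
        assert pct == pytest.approx(75.0)
        assert truth.remaining_fraction == 0.75

    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            FishImageSpec(bands=(BandSpec("x", 300.0, 0.0, 1.0),), side_um=204.8)


class TestDecaySeries:
    @pytest.mark.parametrize(
        "t,t_half,expected",
        [(0.0, 30.0, 1.0), (30.0, 30.0, 0.5), (60.0, 45.0, 2 ** (-4 / 3))],
    )
    def test_noise_free_model_values(self, t, t_half, expected):
        spec = DecaySeriesSpec(times=(t,), t_half=t_half, log_noise_sd=0.0,
                               replicates=1)
        obs = simulate_decay_series(spec)
        assert obs[0].fraction == pytest.approx(expected)

    def test_invalid_half_life_rejected(self):
        with pytest.raises(ValueError):
            DecaySeriesSpec(t_half=0.0)

    def test_round_trip_with_fit(self):
        for t_half in (15.0, 30.0, 45.0, 144.0):
            obs = simulate_decay_series(
                DecaySeriesSpec(t_half=t_half, log_noise_sd=0.0)
            )
            est = fit_half_life(obs)
            assert est.t_half == pytest.approx(t_half, rel=1e-6)
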