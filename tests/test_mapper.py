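"""Aligner correctness, including equivalence with an exhaustive scan oracle."""

import numpy as np
import pytest

from tgkit.dna import encode, random_dna, revcomp_codes
from tgkit.mapper import MapParams, build_index, map_pair, map_pairs
from tgkit.readprep import ReadRecord
from tgkit.synthgen.genome import (
    IntegrationScenario,
    build_reference_set,
    build_transgenic_allele,
)
from tgkit.synthgen.reads import ReadSimParams, simulate_read_pairs

PARAMS = MapParams()


def _read(seq: str, name="r") -> ReadRecord:
    return ReadRecord(name, seq, np.full(len(seq), 40))


def oracle_scan(read_codes: np.ndarray, contigs, p: MapParams):
    """Exhaustive gap-free local alignment over every interior diagonal of
    every contig and strand, with the same scoring and short-tail absorption
    convention as the aligner, written independently of it.

    Returns (best_score, set of (name, pos, lclip, rclip, strand)).
    """
    L = read_codes.size
    best_score = -(10**9)
    placements: set[tuple] = set()
    for name, R in contigs:
        if R.size < L:
            continue
        W = np.lib.stride_tricks.sliding_window_view(R, L)
        n = W.shape[0]
        rows = np.arange(n)
        for strand, rc in (("+", read_codes), ("-", revcomp_codes(read_codes))):
            eq = W == rc[None, :]
            s = np.where(eq, p.match, p.mismatch).astype(np.int64)
            cs = np.cumsum(s, axis=1)
            prefix = np.concatenate([np.zeros((n, 1), np.int64), cs], axis=1)
            runmin = np.minimum.accumulate(prefix, axis=1)
            gains = cs - runmin[:, :-1]
            end = np.argmax(gains, axis=1)
            target = runmin[rows, end]
            start = np.argmax(runmin == target[:, None], axis=1)
            # absorb short unextendable tails, as the aligner does
            a = np.where(start < p.min_clip, 0, start)
            b = np.where((L - 1 - end) < p.min_clip, L - 1, end)
            mne = np.concatenate([np.zeros((n, 1), np.int64), np.cumsum(~eq, axis=1)],
                                 axis=1)
            nm = mne[rows, b + 1] - mne[rows, a]
            score = (b - a + 1 - nm) * p.match + nm * p.mismatch
            m = int(score.max())
            if m > best_score:
                best_score = m
                placements = set()
            if m == best_score:
                for r in np.flatnonzero(score == m):
                    placements.add(
                        (name, int(r + a[r] + 1), int(a[r]), int(L - 1 - b[r]), strand)
                    )
    return best_score, placements


class TestBasics:
    def test_exact_unique_read_maps_full_length(self, refs_default):
        index = build_index(refs_default)
        c12 = refs_default.seq("chr12")
        rec, _ = map_pair(_read(c12[5_000:5_150]), _read(c12[5_300:5_450]), index)
        assert (rec.contig, rec.pos, rec.cigar, rec.mapq) == ("chr12", 5_001, "150M", 60)

    def test_orf_read_is_ambiguous(self, refs_default):
        index = build_index(refs_default)
        tg = refs_default.transgene_seq
        orf_lo = refs_default.tg_layout["orf"][0]
        r = _read(tg[orf_lo + 49: orf_lo + 199])
        rec, _ = map_pair(r, r, index)
        assert rec.mapq == 0
        assert rec.contig in ("chr15", refs_default.transgene_name)

    def test_reverse_strand_read(self, refs_default):
        index = build_index(refs_default)
        c12 = refs_default.seq("chr12")
        from tgkit.dna import revcomp

        rec, _ = map_pair(_read(revcomp(c12[9_000:9_150])), _read(c12[9_300:9_450]), index)
        assert (rec.contig, rec.pos, rec.strand, rec.mlen) == ("chr12", 9_001, "-", 150)

    def test_read_shorter_than_k_is_unmapped(self, refs_default):
        index = build_index(refs_default)
        rec, _ = map_pair(_read("ACGTACGTACGT"), _read("ACGTACGTACGT"), index)
        assert not rec.is_mapped

    def test_k_larger_than_contig_errors(self):
        with pytest.raises(ValueError):
            build_index([("tiny", "ACGTACGT")], k=21)

    def test_proper_pair_flag_from_insert_plausibility(self, refs_default):
        index = build_index(refs_default)
        c12 = refs_default.seq("chr12")
        from tgkit.dna import revcomp

        a, b = map_pair(
            _read(c12[5_000:5_150]), _read(revcomp(c12[5_200:5_350])), index
        )
        assert a.proper_pair and b.proper_pair
        a, b = map_pair(_read(c12[5_000:5_150]), _read(revcomp(c12[25_000:25_150])), index)
        assert not a.proper_pair


class TestSeedIndex:
    def test_key_count_bounded_by_positions(self):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 500)
        index = build_index([("c", seq)], k=21)
        assert len(np.unique(index.kmers)) <= 500 - 21 + 1

    def test_shared_cdna_kmers_hit_two_loci(self, refs_default):
        index = build_index(refs_default)
        orf_lo = refs_default.tg_layout["orf"][0]
        tg = refs_default.transgene_seq
        for off in (0, 200, 800):
            km = index.encode_kmer(encode(tg[orf_lo - 1 + off: orf_lo + 20 + off]))
            cidx, _ = index.lookup(km)
            assert len(set(cidx.tolist())) >= 2


class TestJunctionReads:
    def test_clip_at_junction_without_homology(self):
        sc = IntegrationScenario(h_left=0, h_right=0)
        refs = build_reference_set(5, sc)
        allele = build_transgenic_allele(refs, sc)
        l0 = sc.left_bp - refs.contig("chr12").global_start + 1
        read = allele[l0 - 60: l0 + 90]
        index = build_index([("chr12", refs.seq("chr12"))])
        rec, _ = map_pair(_read(read), _read(read), index)
        assert (rec.pos, rec.cigar) == (l0 - 59, "60M90S")

    def test_clip_extends_through_homology_tract(self, refs_default):
        sc = IntegrationScenario()
        allele = build_transgenic_allele(refs_default, sc)
        l0 = sc.left_bp - refs_default.contig("chr12").global_start + 1
        read = allele[l0 - 60: l0 + 90]
        index = build_index([("chr12", refs_default.seq("chr12"))])
        rec, _ = map_pair(_read(read), _read(read), index)
        # the 4 shared bases align on the chromosome side of the clip
        assert (rec.pos, rec.cigar) == (l0 - 59, "64M86S")


class TestInvariants:
    def test_cigar_consumes_full_read_length(self, default_bundle):
        records = default_bundle.artifacts.records
        for rec in records[:4000]:
            if rec.is_mapped:
                assert rec.lclip + rec.mlen + rec.rclip == len(rec.seq)

    def test_oracle_equivalence_on_500_random_reads(self):
        rng = np.random.default_rng(12)
        contigs = [("cA", random_dna(rng, 3_000)), ("cB", random_dna(rng, 1_500))]
        index = build_index(contigs)
        enc = [(n, encode(s)) for n, s in contigs]
        params = ReadSimParams(coverage=51.0, seed=4)   # ~765 pairs over 4.5 kb
        r1, r2, _ = simulate_read_pairs(contigs, params)
        pairs = list(zip(r1, r2))[:250]
        records = map_pairs(pairs, index)
        mismatches = 0
        for i, (m1, m2) in enumerate(pairs):
            for read, rec in ((m1, records[2 * i]), (m2, records[2 * i + 1])):
                _, placements = oracle_scan(encode(read.seq), enc, PARAMS)
                if not rec.is_mapped:
                    mismatches += 1
                    continue
                if (rec.contig, rec.pos, rec.lclip, rec.rclip, rec.strand) not in placements:
                    mismatches += 1
        assert mismatches == 0

    def test_error_free_unique_reads_map_at_source(self):
        rng = np.random.default_rng(7)
        contigs = [("c", random_dna(rng, 5_000))]
        index = build_index(contigs)
        params = ReadSimParams(coverage=10.0, error_scale=0.0, seed=3)
        r1, r2, truth = simulate_read_pairs(contigs, params)
        records = map_pairs(list(zip(r1, r2)), index)
        by_name = {}
        for rec in records:
            by_name.setdefault(rec.qname, []).append(rec)
        for _, row in truth.iterrows():
            m1 = next(r for r in by_name[row.pair_id] if r.mate == 1)
            assert (m1.contig, m1.pos, m1.mlen) == ("c", row.frag_start, 150)
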