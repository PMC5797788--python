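# Methods

This note documents the models behind tgkit, the parameter defaults and why
they were chosen, what the synthetic data do and do not emulate, and the
numerical conventions that matter for reproducing its output.

## 1. The synthetic genome

Real chromosomes are replaced by desk-scale windows addressed in global
coordinates, so printed chromosome-scale positions are reproduced without
an 80-Mb simulation:

| contig | models | length | global offset |
|---|---|---|---|
| `chr12` | integration neighbourhood | 80 kb | Chr12:78,100,001 |
| `chr15` | endogenous *Arc* locus (74,669,000–74,682,000) | 30 kb | Chr15:74,660,001 |
| `chr6`  | single-copy control (gapdh-like) window | 150 kb | arbitrary |
| transgene | the 11,829-bp reporter construct | 11,829 bp | — |

The transgene is promoter (7,000 bp) + *Arc* 5′UTR (200 bp) + EGFP marker
(750 bp) + *Arc* ORF (1,200 bp) + *Arc* 3′UTR (2,679 bp); only the 11,829-bp
total is a fixed biological datum, the component split is a package default.
The UTRs and ORF are literal copies of the chr15 gene body because the real
construct carries *Arc*'s own cDNA; this reproduces the multi-mapping
ambiguity between the transgene array and the endogenous locus that both
the informative-pair extraction and the copy-number estimator must handle.
Promoter and EGFP are random sequence and therefore unique anchors.  The
control window is deliberately long (150 kb): the depth normalizer should
contribute less counting error (~0.8% CV at 13.5×) than the shared-cDNA
signal itself (~1.3% CV), a precision budget fixed before any estimates
were run.

**Transgenic allele.**  `chr12[1..left_bp] + transgene×C + chr12[right_bp..]`
with defaults left_bp 78,137,441, right_bp 78,139,250 (1,808-bp deletion),
C = 15, orientation `+` (the array orientation is not a measured quantity;
it is configurable).  Zygosity selects the diploid mixture (hemizygous =
one transgenic + one wild-type allele).

**Microhomology planting.**  The first h_left bases of the inserted unit
are overwritten with the first h_left deleted chr12 bases, and its last
h_right bases with the last h_right deleted bases (defaults 4 and 5).  A
deterministic repair loop then resamples a few *free* bases — retained
flank adjacent to the junction, deleted bases just beyond the tract, insert
interior — until (a) the maximal shared tract measured by the same
functions the caller uses equals the planted h on both sides, and (b)
greedy ungapped extension across each junction stops exactly at the tract
end.  Without this, homopolymers or chance matches can make the planted
scenario genuinely ambiguous; the repair makes "planted value" and "true
value" identical by construction rather than with high probability.

## 2. Read simulation

Uniform fragment starts, normal insert sizes (350 ± 50 bp, a typical
PCR-free library; configurable), 150-bp mates in FR orientation.  Fragments
shorter than the read length read through into the TruSeq adapter.
Qualities follow a per-cycle mean profile (q37 with a 3′ taper to q33,
scatter sd 3) and substitutions are injected at the Phred-implied rate;
there are **no indel errors** (a documented limitation — soft-clip logic
does not need them, and the mapper is correspondingly gap-free).
`coverage` applies per listed haplotype; the pipeline lists both copies of
each diploid window with coverage/2, so the default 13.5 means diploid
genome depth, matching the sequenced library.

## 3. Mapping

Exact 21-mer seeds at three read offsets per strand; candidate diagonals
are extended without gaps (match +1, mismatch −4) keeping the best-scoring
contiguous window; terminal tails shorter than 8 bp that cannot extend are
absorbed into the match, longer ones become soft clips.  The mapq surrogate
is binary — 60 unique, 0 tied — because downstream logic only distinguishes
unique from ambiguous; ties break deterministically by contig order, then
leftmost coordinate.  On the synthetic references the aligner is verified
against an exhaustive scan over every diagonal (the gap-free reduction of
Smith–Waterman, matching the error model).  At real scale any aligner can
substitute: the caller consumes SAM via `tgkit.samio`.

## 4. Integration calling

1. **Informative pairs**: a mate on the transgene contig or inside the *Arc*
   locus interval, mapq 0 included.
2. **Candidate region**: densest 4-kb window of counterpart mates (non-
   transgene, outside the *Arc* locus ± 2 kb), needing ≥ 4 pairs, padded to
   8 kb.  The 4-kb window is sized to merge the two junction-mate clusters,
   which sit deletion + 2·insert ≈ 2.5 kb apart.
3. **Coverage gap**: homozygous mode takes the longest run of zero M-base
   depth ≥ 500 bp.  Hemizygous (depth-drop) mode first smooths depth over a
   500-bp window — per-base depth at 13.5× fluctuates far too much for a
   contiguous sub-median run — and flags smoothed depth < 0.75 × the region
   median, the midpoint between the one-allele (0.5) and two-allele (1.0)
   levels.  Junction reads carry the homology bases, so the homozygous gap
   is about `deletion − h_left − h_right` long, and absorbed sub-8-bp tails
   can nibble a few more bases off its edges.
4. **Breakpoints**: junction evidence is harvested in both directions —
   chromosome-anchored reads whose clipped tail matches a transgene
   terminus (≤ 1 mismatch over up to 40 bases, insert offsets 0..30), and
   transgene-terminus-anchored reads whose clipped tail locates in the
   region by a unique exact 25-bp anchor.  Each read casts one breakpoint
   vote (clip position corrected by the per-read homology measurement for
   chromosome-anchored reads); consensus is the best-supported position,
   ties toward more reads then leftmost.  The reported h is the maximal
   shared tract at the consensus breakpoint; by the attribution convention
   `left_bp + h_left` and `right_bp − h_right` equal the clip consensus
   positions.  Fewer than 2 supporting reads on either side sets a
   low-confidence flag.  Zygosity: gap depth < 0.1 × flank median ⇒
   homozygous.
5. **Secondary scan**: clusters (≥ 3 pairs) of transgene-anchored mates
   outside the known site ± 5 kb and the *Arc* locus halo.

At the default conditions each junction collects ~5–20 evidence reads and
recovery of (left_bp, right_bp, h_left, h_right) is exact in 20/20
replicate libraries; at 2× coverage the low-confidence flag engages.

## 5. Copy number

**Read depth.**  Every read sequenced from any copy of the shared Arc cDNA
lands, at its homologous offset, in one of the annotated shared intervals
(transgene 5′UTR, transgene ORF+3′UTR, chr15 gene body) regardless of how
multi-mapping ties are broken — so the *sum of M-bases over all shared
intervals divided by the shared length per copy* (4,079 bp) is a conserved
estimate of total copy-depth.  Then
`total_copies = 2 × copy_depth / control_mean_depth` and
`per_locus = (total − 2)/n_loci` (n_loci 1 hemizygous, 2 homozygous).
Normalizing instead by pooled mean over the intervals would halve the
estimate, since the same cDNA is annotated on two contigs.  mapq-0
alignments are deliberately included; excluding them deflates the estimate.
Bias is ≤ 0.5 copies across C ∈ {1, 5, 15, 30} at 13.5×, with a counting
CV of ~1.5–2% (≈ 0.25–0.85 copies sd depending on C).

**qPCR.**  `Ct = baseline − log_E(copies/2) + ε`, reference state the WT
diploid.  Defaults: E = 2, 3 technical replicates, replicate scatter
ε ~ N(0, 0.03 cycles) — a well-optimized SYBR assay on purified genomic
DNA — and a 16-animal cohort (5 WT / 5 hemizygous / 6 homozygous) matching
the study's genotyping design.  Estimation is standard ΔΔCt against the WT
calibrators.  At these defaults the plate-level ΔΔCt precision (~0.015
cycles) resolves a single copy at C = 15.

## 6. FISH images and quantification

Stacks are laminar bands of base labeling intensity with Poisson-placed
puncta (2-D Gaussians of PSF σ, spread across z with σ_z 0.45 µm), an
optional circular transcription-block region scaled by the remaining
fraction f (damage core, default 150 µm, scaled harder and excluded from
measurement), then Poisson shot noise and Gaussian read noise.  Because the
f-scaling precedes noise, the planted ratio is exact in expectation.

Three presets mirror the imaging designs: the 63× confocal puncta field
(204.8 µm side — the study reports "204.8 µm²", dimensionally a side
length — 0.2 µm/px, 4 slices 0.55 µm apart), and two 20× wide-field
single-plane presets for lamina profiles and Act-D regions (the 4-slice
stack design belongs to the 63× acquisitions; max-projecting noisy
replicate planes would also bias the region ratio upward by ~1 point).
Band widths, densities and intensity levels are package defaults chosen to
look like dentate-gyrus FISH; none is a measured quantity.

Puncta counting follows the ImageJ recipe: min–max rescale to 8 bit,
invert (retained for fidelity; mathematically inessential), threshold
(default: background mean − 4 sd on the inverted image, replacing the
study's per-image manual adjustment; reported in the output), 8-connected
components, minimum area 4 px.  Two puncta closer than ~2 PSF widths merge
and count once — recovery is exact for well-separated plantings and within
5% at the default density.  Line profiles sample bilinearly every 10 µm
along ~10 parallel placements and average; the MML anchor sits at 150 µm
(300-µm ROI) or 125 µm (250-µm ROI).  The region ratio is
`100 × mean(region ∖ core) / mean(outside region)`.

What the generator does **not** emulate: optical aberrations, uneven
illumination, section-to-section registration, autofluorescence, nuclear
transcription foci, or cell bodies as segmentable objects.  Passing tests
therefore validate the quantification algorithms against their own model,
not microscope physics.

## 7. Decay kinetics

First-order decay, `fraction(t) = 2^(−t/t½)`, with multiplicative
log-normal noise (sd 0.1) in the generator.  The estimator is
zero-intercept least squares on ln f vs t —
`t½ = −ln2 · Σt² / Σ(t·ln f)` — because ratio-to-surround normalization
pins the fraction to 1 at t = 0; a free-intercept variant exists for
diagnostics.  Fractions > 1 are retained (clipping would bias the fit);
a fitted rate ≥ 0 raises a no-decay error.  The standard error propagates
the residual variance through the delta method.  The default series (15,
30, 45, 60 min; t½ 45 min) mirrors the cultured-neuron time course; an
in-vivo preset (30/60 min, t½ 30 min) mirrors the blockade design.  The fit
is exact on noise-free data and the median over 100 noisy series is within
5% of truth.

## 8. Reproducibility and scale

All randomness flows from explicit seeds; pipeline stages receive children
of one top-level `SeedSequence`, so equal seeds give byte-identical
references, reads, tables and images.  Problem sizes (80/30/150-kb windows,
13.5× depth → ~20k read pairs; 512–1024-px images) were chosen so a full
end-to-end run completes in seconds on one CPU while keeping every printed
coordinate on its real chromosome scale.  Statistical summaries are group
means/medians with dispersion; hypothesis testing (ANOVA etc.) is out of
scope.
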