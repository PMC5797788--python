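# tgkit

Computational companion to a transgenic-mouse study of dendritic mRNA
trafficking: given whole-genome sequencing of a line carrying a multi-copy
*EGFP-Arc* reporter, find where the transgene landed; given fluorescence
in-situ hybridization (FISH) images after transcriptional blockade, measure
how fast the reporter mRNA decays.  The package is aimed at readers who want
to reproduce, probe, or reuse the analysis: every input is generated
synthetically with known ground truth, so each estimator can be validated
end to end.

## What it computes

**Genomics arm.**  A tandem multi-copy transgene insertion replaces a
stretch of chromosome 12, deleting `right_bp − left_bp − 1` bases.  From
150-bp paired-end reads at 13.5× the pipeline: trims adapters and low-quality
ends (q < 16) and drops pairs with a mate < 36 nt; maps reads with a
seed-and-extend aligner (external SAM is accepted equivalently); extracts
*informative pairs* (a mate on the transgene or the endogenous *Arc* locus,
multi-mapping hits included); clusters their counterpart mates into a
candidate region; finds the deletion as a coverage gap; and resolves both
breakpoints to single-base precision from soft-clipped reads.  Junction
microhomology is the maximal tract shared by the transgene terminus and the
adjacent chromosomal sequence, attributed to the transgene, so that

```
left_bp  = last retained chr12 base      h_left  = |shared tract, left junction|
right_bp = first retained chr12 base     h_right = |shared tract, right junction|
deletion = right_bp − left_bp − 1
```

Copy number per locus comes from two independent routes: pooled read depth
over the Arc-cDNA intervals shared by transgene and endogenous locus,
normalized to a single-copy control window, and a ΔΔCt qPCR emulation
(`copies_total = 2·E^{ΔΔCt}`, ΔCt = Ct(control) − Ct(ORF)).  An in-silico
PCR utility checks junction/WT primer sets.

**Imaging/kinetics arm.**  Maximum-intensity projection, ImageJ-style
puncta counting (8-bit rescale → invert → threshold → connected
components), averaged line profiles across the dentate laminae, and the
region-of-blockade remaining fraction (mean intensity in the Act-D region,
damage core excluded, as % of the surround).  Half-lives follow first-order
decay, `fraction(t) = 2^(−t/t½)`, estimated by zero-intercept least squares
on ln(fraction) vs t.

## Worked example

```
$ python analysis/01_integration_site.py --seed 1
pairs simulated: 19604 (kept 19604)
planted   : chr12:78137441/78139250 deletion 1808 bp, homology 4/5 bp, homozygous
recovered : chr12:78137441/78139250 deletion 1808 bp, homology 4/5 bp, homozygous (support 6/7 reads)
secondary sites: 0
```

The caller recovered both breakpoints exactly — an 1,808-bp deletion with
4- and 5-bp junction microhomologies — from 6 and 7 split reads per
junction, and found no other integration anywhere in the genome.

```
$ python analysis/02_copy_number.py --seed 1
depth  C= 1: estimated   0.80 (rounded 1)
depth  C= 5: estimated   4.99 (rounded 5)
depth  C=15: estimated  14.87 (rounded 15)
depth  C=30: estimated  29.21 (rounded 29)
qpcr   hemi_1 (hemizygous):  15.12 (rounded 15)
qpcr   homo_1 (homozygous):  14.73 (rounded 15)
```

Both routes agree with the planted 15 copies per locus; the depth estimator
stays within one copy across a 30-fold range of array sizes.

```
$ python analysis/04_decay_halflife.py --seed 1
noise-free culture series: t1/2 = 45.0000 min (truth 45)
100 noisy series (log-sd 0.1): median t1/2 = 45.26 min, sd 2.07
```

`analysis/03_fish_quantification.py` runs the imaging quantifications
(puncta recovery, lamina profiles, and the Act-D region ratio, e.g. planted
75% → measured 74.99 ± 0.07%).

## Layout

```
src/tgkit/           library: synthgen/ (generators), readprep, mapper,
                     integration_caller, copy_number, fish_quant,
                     decay_kinetics, pipeline, samio, coverage
analysis/            numbered narrative drivers writing results/
tests/               pytest suite (unit, property and acceptance tests)
docs/methods.md      models, parameter choices, and limitations
```
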