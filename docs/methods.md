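# Methods

## Scope and data model

The package analyzes aligned ribosome footprints, not raw sequencing
reads: its inputs are ORF annotations (tab-separated intervals plus a
genome FASTA) and footprint records identified by contig, strand, footprint
length, and the genome coordinate of the 3'-most aligned base. Read
trimming, rRNA/tRNA subtraction and genome alignment are upstream concerns
of standard tools and are deliberately outside the package. Coordinates are
0-based half-open internally; reports are 1-based inclusive.

The 3' end is the anchor because bacterial ribosome-protected fragments
have a sharply defined 3' boundary: the decoded (A-site) codon begins a
fixed offset Δ upstream of it.

## Filters and density

Footprints of 15–40 nt (inclusive bounds) are retained. Density is 3'-end
counts per nucleotide in RPM (reads per million retained alignments). ORFs
enter the analysis when they are at least 170 nt long and average at least
1 raw footprint per codon (0.33 per nt); the count threshold is applied to
raw counts rather than RPM because "one footprint per codon" is only
meaningful pre-normalization, and it is evaluated over the full ORF before
end-trimming. Analysis windows exclude the first 50 nt and last 20 nt of
each ORF, removing initiation- and termination-proximal signal. The
170-nt floor guarantees a non-empty window.

Policy choices where conventions differ: duplicate read identifiers are an
error (inputs are assumed uniquely mapped); a 3' end falling inside two
overlapping same-strand ORFs is counted for both, a transparent,
auditable double-counting recorded in the filter report.

## A-site offset calibration

A single global offset Δ is used for all read lengths. Calibration
exploits a hard boundary of elongation: no A site can precede the start
codon, so the ORF-local 3'-end metagene (each gene normalized by its own
mean, then averaged over genes) is exactly zero on `[0, Δ)` and spikes at
Δ. For each candidate Δ in 5–20 nt the edge score is the metagene value at
Δ minus the mean over the 3 nt upstream; the maximizing candidate wins and
ties prefer the smaller Δ. Because in-frame 3' ends occupy every third
nucleotide, wrong candidates either include the true spike in their
upstream penalty or sit on zero density, so the true Δ dominates. The
stop-anchored profile cannot pin Δ absolutely (ORF-local tracks truncate
at the last nucleotide) but its last occupied position fixes Δ modulo 3;
this reading-frame consistency flag is reported. A flat profile (no
initiation edge, e.g. uniform density) raises a calibration error advising
a manually supplied offset. Calibration refuses to run on fewer than 10
genes.

## Pause scores

`score(i) = density(i) / mean(density over the trimmed window)`, giving
every profile a window mean of exactly 1 and making scores invariant to
library depth and gene expression. The denominator uses the trimmed
window, not the full ORF, so the mean-one invariant holds on exactly the
positions analyzed. A codon occurrence's A-site pause score is the mean of
the three per-nucleotide scores at its offset-shifted positions;
occurrences whose shifted positions leave the window are skipped and
counted. Codon rows aggregate occurrences across genes; amino-acid rows
are occurrence-weighted means of their codons. A `top_n` option restricts
the table to the first n genes (by identifier) when emulating analyses of
the most heavily translated genes; the default uses all included genes.

A small coordinate utility converts toeprinting (primer-extension) stall
positions to A-site codon starts: reverse transcriptase stalls 13 nt
downstream of the first nucleotide of the stalled ribosome's A-site codon,
so `a_site = stall − 13` in the input's own 1-based coordinates.

## Compositional comparison

Each gene window is partitioned into 10 contiguous bins of near-equal
length; the `window mod 10` leftover nucleotides are assigned one each to
the 3'-most bins (a deterministic, documented bias direction). Per-bin
density percentages form a 10-part composition (closure to 100). Zero
parts are repaired by multiplicative simple replacement: each zero becomes
65% of the composition's smallest nonzero part (floor 1e-6), followed by
re-closure — standard compositional practice when zeros are sampling
artifacts rather than structural.

The ilr transform uses an orthonormal contrast basis; the default
("pivot-1") is the sequential-binary-partition pivot basis in bin order,
and a normalized Helmert basis is available. Hotelling's T² is invariant
to this choice (asserted to 1e-8 in the tests), so the basis only matters
for interpreting individual coordinates. The paired test computes
T² = n·d̄ᵀS⁻¹d̄ on ilr differences with the usual F mapping
F = T²(n−p)/(p(n−1)), df = (p, n−p), p = 9. Identical paired samples
short-circuit to T² = 0, p = 1 (their covariance is singular but the
difference is exactly zero); any other singular covariance is an error
suggesting fewer bins. Geometric means (re-closed to 100) summarize
condition profiles.

Normality of ilr coordinates is assessed with Mardia's skewness and
kurtosis statistics (skewness n·b₁ₚ/6 ~ χ² with p(p+1)(p+2)/6 df;
kurtosis z-test of b₂ₚ against p(p+2), ML covariance), combined by
Bonferroni. The exact goodness-of-fit procedure used in compositional R
packages is not uniquely defined, so Mardia's classical pair was chosen;
the result is advisory and never gates the pipeline.

## Synthetic footprint generator

The generator produces the statistical structure the analysis assumes,
with defaults chosen to mimic a bacterial Ribo-seq experiment at desk
scale:

- ORFs: 50 genes of 120–320 codons (uniform), ATG start, TAA stop, no
  internal stops, codon usage uniform over the 61 sense codons unless
  configured; laid on one contig with 100-nt spacers, + strand by default
  (a both-strands switch alternates strands to exercise strand logic).
  A variant generator fixes the per-gene fraction of codons for one amino
  acid exactly, for closed-form oracles.
- Footprints: count at sense codon k ~ Poisson with mean ∝
  `dwell(codon_k)·(1−q)^k`; drop-off is memoryless per codon (geometric
  survival), the simplest model generating a monotone 3' decline. The 3'
  end sits exactly Δ nt (default 11) downstream of the A-site codon's
  first nucleotide; an optional ±1 nt jitter tests calibration
  robustness. Lengths are a rounded Gaussian (mean 25, sd 3) truncated to
  15–40 nt — the admissible range is known but the in-range shape is a
  stand-in — and resampled to exceed Δ. Default depth is 100k footprints
  (2k per gene, ≈9 per codon), comfortably above the 1-per-codon filter,
  as in a well-covered bacterial library.
- The paired fixture: "toxin" = Gly dwell ×5 with q = 0.004; "control" =
  Ser dwell ×2 (the hungry-Ser artifact of cell harvest), q = 0; both over
  a shared gene set, 40 genes at 200k footprints.

What the simulator does *not* model: sequencing error, mapping ambiguity,
duplicates/UMIs, per-length offset variation, biased nuclease trimming,
or real codon-usage correlation structure. Passing tests therefore show
the analysis chain is correct under its stated model, not that real
libraries are free of these artifacts.

## Mass model

Average masses are built from elemental composition (H 1.008, C 12.011,
N 14.007, O 15.999, P 30.974): nucleosides + 61.965 Da per phosphodiester
linkage + 79.980 Da per terminal phosphate (cyclic = linear − 18.015) +
adducts + 1.008 for MH⁺. Monoisotopic masses are available but average is
the default, matching linear-mode MALDI-TOF. Internal digest fragments
default to 5'-OH / 3'-linear-phosphate (the hydrolyzed cyclic
intermediate); the 3'-terminal fragment keeps the molecule's native
terminus. Guanosines listed as protected are exempt from cleavage,
modeling modified or inaccessible G residues — the tRNA-Gly 3'-terminal
fragment UUUCCCGCUCCA contains such an internal G. A printed "T" in an RNA
sequence is read as unmodified U: this reproduces the measured MH⁺ of
3670 within 1 Da, whereas ribothymidine (+14 Da) would not, an
internal-consistency check on the fragment's reported identity. Adducts
are additive and sequence-independent: glycyl +57.05 Da (Gly residue),
acetyl +42.04 Da (valid only on an aminoacyl adduct, since acetylation
blocks the amino acid's alpha-amino group, not the RNA); peptidyl-tRNA
hydrolase removal restores the unmodified mass exactly. Peak matching is
nearest-theoretical within a 1 Da tolerance, ties to the lower mass.

## Benchmark problem sizes

The evaluation experiments use: offset recovery — 5 offsets × 4 seeded
replicates, 20 genes, 60k footprints each; Gly pause oracle — 40 genes at
exact 10% Gly, 1M footprints (the closed form m/(f·m+1−f) = 3.571 at
m = 5, f = 0.1, checked within 3 standard errors of the occurrence mean);
Hotelling calibration — 500 null and 100 alternative replicates of 50
paired genes at 100k footprints, via the simulator's per-codon Poisson
count path (identical generative model, skipping per-read bookkeeping so
hundreds of replicates stay cheap). These sizes are the package's own
defaults and are reproduced by `scripts/acceptance.py` from a single seed.

## Known limitations

- The calibration requires the sharp initiation edge the 3'-end anchor
  provides; libraries with heavy 3'-end heterogeneity would need the
  jittered simulator mode and possibly per-length offsets, which are out
  of scope.
- The compositional test assumes approximate multivariate normality of
  ilr differences; at very low coverage Poisson discreteness inflates
  tails (the Mardia report flags this), so the per-codon count defaults
  keep bins well populated.
- Overlap double-counting slightly inflates densities in operonic
  overlaps; the filter report exposes the affected counts.
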