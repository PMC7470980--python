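# ribopause

Desk-scale analysis toolkit for studying codon-specific ribosome stalling
from ribosome profiling (Ribo-seq) data, built around the biology of
GNAT-family toxin–antitoxin toxins that acetylate the aminoacyl moiety of a
charged tRNA and thereby starve the ribosome of one amino acid. The package
answers two questions with fully reproducible, simulation-backed analyses:

1. **Where do ribosomes stall?** From aligned footprint 3' ends it computes
   per-nucleotide densities, calibrates the A-site offset, derives pause
   scores, and compares the positional distribution of ribosomes between
   conditions with a paired compositional test.
2. **What is the chemical lesion on the tRNA?** An in-silico RNase T1
   digestion and average-mass MH+ calculator reproduces the
   mass-spectrometric signature of aminoacylation (+57 Da for glycyl) and
   alpha-amino acetylation (+42 Da) of a tRNA-Gly 3'-terminal fragment.

It is aimed at bacterial translation labs who want the complete analysis
chain — filters, offset calibration, pause scores, compositional statistics,
mass matching — as a tested library rather than a collection of one-off
scripts.

## Methods at a glance

- **Density.** Ribosome density is the number of footprint 3' ends per
  nucleotide, normalized by the total number of uniquely mapped reads in
  millions (RPM). Footprints of 15–40 nt are kept; ORFs shorter than 170 nt
  or with mean raw density below 1 footprint per codon (0.33/nt) are
  excluded, and the first 50 nt / last 20 nt of each ORF are trimmed from
  all downstream windows.
- **A-site assignment.** The codon being decoded sits a fixed offset Δ
  upstream of the footprint 3' end (default 11 nt). Δ is calibrated from
  start/stop-anchored metagene profiles: density cannot appear upstream of
  the initiation codon, so the start-anchored profile rises abruptly at
  position Δ.
- **Pause score.** For nucleotide *i* of a gene window,
  `s(i) = d(i) / mean(d)`, so every profile has window mean 1. A codon's
  A-site pause score averages the three nucleotides it projects onto; codon
  and amino-acid tables aggregate over all occurrences.
- **Positional comparison.** Each gene window is cut into 10 equal bins and
  summarized as the percentage of density per bin — a 10-part composition.
  After isometric log-ratio (ilr) transformation with an orthonormal pivot
  basis, matched genes from two conditions are compared with a paired
  Hotelling T² test (`F = T²(n−p)/(p(n−1))`, p = 9); geometric means
  summarize each condition's profile. Mardia's multivariate normality
  checks are reported advisorily.
- **Mass model.** Average masses from elemental composition: nucleosides +
  61.965 Da per phosphodiester + terminal adjustments + adducts
  (glycyl = Gly residue C₂H₃NO = 57.05 Da; acetyl = C₂H₂O = 42.04 Da) +
  1.008 Da for MH⁺, matched against observed peaks at 1 Da tolerance.
- **Simulator.** Expected footprint count at sense codon *k* is
  `dwell(codon_k) · (1−q)^k` (Poisson), with q a per-codon drop-off
  probability producing a 3'-ward density decline; 3' ends sit Δ nt
  downstream of the A-site codon's first nucleotide. A truth table enables
  round-trip parameter recovery tests.

## Worked example

Generate the paired synthetic conditions — a "toxin" dataset with 5-fold
Gly dwell and per-codon drop-off q = 0.004, and a "control" with 2-fold Ser
dwell — then run the full paired analysis:

```
python analysis/01_simulate_conditions.py
python analysis/02_run_pipeline.py
```

which prints:

```
calibrated A-site offset: 11 nt
paired ORFs: 40
paired Hotelling T2 = 286.3, F(9,31) = 25.3, p = 6.99e-12
toxin: strongest A-site pausing at G (mean pause score 3.95)
control: strongest A-site pausing at S (mean pause score 1.80)
toxin geometric-mean profile bin1 -> bin10: 14.1% -> 6.6%
```

The calibration recovered the simulator's 11-nt offset; the toxin condition
stalls ribosomes with Gly codons in the A site while the control shows the
milder "hungry Ser" pausing; and the drop-off produces a declining
geometric-mean density profile whose difference from the control is highly
significant under the paired T² test.

The mass-spectrometry side (`python analysis/05_trna_mass_series.py`):

```
      species  mh_plus
   unmodified   3669.2
       glycyl   3726.3
acetyl-glycyl   3768.3
    after_pth   3669.2
```

Glycylation of the tRNA-Gly 3'-terminal T1 fragment UUUCCCGCUCCA adds
57 Da, toxin-mediated acetylation another 42 Da, and peptidyl-tRNA
hydrolase returns the fragment to its unmodified mass — the diagnostic
signature of alpha-amino acetylation of Gly-tRNA.

A `ribopause` console command exposes the same stages
(`simulate`, `make-fixtures`, `run-all`, `msdigest`); see `ribopause --help`.

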