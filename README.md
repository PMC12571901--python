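# phageaso

Antisense-oligomer (PNA) design and knockdown-screen analytics for phage
functional genomics.

Many phages — including jumbo phages such as ΦKZ of *Pseudomonas
aeruginosa* — are not amenable to genetic knockouts, so gene function can
instead be probed by *translational silencing*: a short peptide nucleic acid
(PNA) antisense oligomer (ASO), delivered with a cell-penetrating peptide,
base-pairs with the ribosome binding site of a target mRNA and blocks
initiation. `phageaso` implements the computational side of such a screen:

- **TIR extraction** — strand-corrected translation-initiation-region windows
  around each annotated start codon, in signed mRNA coordinates (no position
  0; +1 is the A of the AUG), from GenBank or FASTA+GFF3 input.
- **ASO design** — enumeration of 11-mer (configurable) antisense candidates
  over a TIR, scored for predicted PNA/DNA melting temperature
  (nearest-neighbor duplex Tm plus a linear PNA correction), purine fraction
  and self-complementarity, then filtered (Tm 45–55 °C, purine 25–35 %,
  < 3 off-target TIRs, low self-complementarity) and ranked, requesting at
  least two passing ASOs per gene.
- **Off-target scanning** — ungapped mismatch-tolerant (Hamming) search of
  each candidate's target site across all phage and host TIRs, with
  distinct-TIR counting stratified by mismatch level (0–4), an exact
  brute-force path and an equivalent pigeonhole-seeded accelerator, and a
  closed-form binomial null for chance hits.
- **Tiling and controls** — dense tiling of a widened window (−37..+44 by
  default: 71 candidates) for empirical mapping, and central-mismatch
  negative controls (e.g. two central mismatches on an 11-mer).
- **Screen analytics** — serial-dilution spot counts → CFU/PFU titers
  (most dilute countable spot, censoring at the detection limit), ordinal
  effect categories (none/+/++/+++/− from log10 titer reduction), early vs
  middle/late transcript classification (|log2FC| > 2 and −log10 adj. P > 10),
  and gene × knockdown log2FC matrices for clustering.
- **Synthetic fixtures** — seeded generators for annotated genomes with
  planted Shine–Dalgarno motifs, Poisson spot-count tables with planted
  effects, and expression tables with planted temporal classes, so the whole
  stack is testable without downloads.
- **Homology utility** — global protein percent identity (BLOSUM62, affine
  gaps), with the denominator conventions reported explicitly.

## Worked example

```bash
# a seeded synthetic genome with planted Shine–Dalgarno motifs
phageaso simulate genome --n-genes 8 --seed 42 --out demo/

# design ASOs for one gene
phageaso design --genome demo/SYNTH_42.fasta --annotation demo/SYNTH_42.gff3 \
    --genes SYN_0001 --out demo/design.tsv
```

The top passing candidates for `SYN_0001` (3 of 35 pass the full filter):

```
    gene  site_from  site_to     aso_seq  tm_c  purine_frac  selfcomp  cum_mm2  passes  rank
SYN_0001        -18       -8 CCTCCTGTCAG  50.9       0.2727         3        0    True     1
SYN_0001        -19       -9 CTCCTGTCAGC  52.0       0.2727         3        0    True     2
SYN_0001         -6        5 ATCATCGTCTT  45.9       0.2727         2        0    True     3
```

The rank-1 ASO sits directly over the planted SD motif (site −18..−8), has a
predicted Tm of 50.9 °C (inside the 45–55 °C band), 27 % purines (inside
25–35 %), and zero off-target TIRs within two mismatches (`cum_mm2`). A
matched negative control with two central mismatches:

```bash
$ phageaso mismatch-control --aso CCTCCTGTCAG --k 2
CCTCATTTCAG
```

Other commands: `phageaso tile` (scored −37..+44 tiling), `phageaso
offtarget`, `phageaso screen` (spot counts → effect categories), `phageaso
classify` (temporal classes), `phageaso pid` (protein percent identity),
`phageaso simulate screen|expression`.

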