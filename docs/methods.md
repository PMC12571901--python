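# Methods

This note records the models, parameter choices and numerical conventions
behind `phageaso`, and what the synthetic-data tests do and do not
demonstrate.

## Coordinates and TIR windows

Annotations are 1-based inclusive (GenBank/GFF3 convention). mRNA offsets
around the start codon skip position 0: +1 is the first base of the AUG, −1
the base immediately 5′ of it, so a window −37..+44 spans 81 nt and tiles
into 71 11-mers. Minus-strand genes are reverse complemented so every TIR
sequence reads 5′→3′ on the mRNA. Genomes are treated as linear: windows
are clipped at contig ends with a warning and flagged `truncated`, never
wrapped — the reference records this tool targets are linear flat files,
and circularly permuted starts are rare enough at TIR scale to flag rather
than resolve. Joined (multi-exon) CDS locations are flagged `compound` and
only the outer span is used; interrupted phage genes require manual
attention and are deliberately not auto-resolved. Windows containing N are
carried through extraction but excluded from design.

The default design window is −30..+15: wide enough to cover any
Shine–Dalgarno placement plus the early coding region, narrower than the
−37..+44 tiling window used for empirical mapping (tiling is exposed
separately and unfiltered).

## PNA melting temperature

The screen's Tm filter (45–55 °C) needs a pinned, reproducible predictor.
We use the standard two-step model for PNA/DNA duplexes:

1. DNA/DNA nearest-neighbor Tm of the oligomer against its perfect
   complement, with the unified duplex parameter set (10 dinucleotide
   ΔH/ΔS pairs plus terminal-pair initiation terms), evaluated at 4 µM
   total strand and 1 M Na⁺ (no salt correction):
   Tm = ΔH / (ΔS + R ln(C_T/4)).
2. The published linear PNA/DNA regression
   Tm_PNA = 20.79 + 0.83·Tm_NN − 26.13·f_pyr + 0.44·L,
   where f_pyr is the pyrimidine fraction of the PNA strand and L its
   length.

All coefficients live in a versioned `TmModel` dataclass so alternative
parameterizations can be swapped wholesale. Values are reported to 0.1 °C.
Tests cross-check the NN sum against Biopython's independent implementation
at matched conditions and against a hand-summed 8-mer. Mismatched-duplex
thermodynamics are out of scope; `melting_temperature` refuses
non-complementary pairs.

Note an asymmetry inherent to the model: the underlying DNA/DNA NN Tm is
invariant under reverse-complementing both strands, but the PNA correction
is not — it depends on which strand is the PNA (via f_pyr). The duplex
symmetry test therefore applies to the NN layer.

## Design filter and ranking

A candidate passes iff Tm ∈ [45, 55] °C, purine fraction ∈ [0.25, 0.35],
self-complementarity ≤ 5 nt, and the number of distinct off-target TIRs at
≤ 2 mismatches (target excluded) is < 3. Purine fraction is scored on the
ASO strand: the two strands are complementary, so a low-purine ASO is
exactly the complement of a purine-rich (SD-like) target site, and the
printed band (25–35 %) is only discriminative on the ASO side.
Self-complementarity is the length of the longest substring whose reverse
complement also occurs in the sequence (exhaustive scan); the 5-nt default
threshold is our choice — the criterion is standard but unnumbered in the
design literature.

Ranking is deterministic and explicit: fewest off-target TIRs at the
criterion level, then |Tm − 50 °C|, then site centre closest to the start
codon, then 5′-most site; passing candidates precede failing ones, and
stable sorting makes output byte-identical across runs. Genes with fewer
than two passing candidates are flagged under-designed rather than
silently padded.

### Why the off-target rule is applied at ≤ 2 mismatches

The screen's off-target criterion ("< 3 distinct TIRs") is only meaningful
at a mismatch level where chance hits are rare. For an 11-mer against a
46-nt TIR, the per-TIR chance-hit probability under a uniform-base null is
1 − (1 − p)^36 with p = Σ_{k≤m} C(11,k)3^k/4^11. At m = 4 this gives an
expected ~60+ chance TIR hits across a ~370-gene phage — every candidate
would fail. At m = 2 the expectation is ≈ 1.7, so exceeding 3 is
informative. Counts at 0..4 mismatches are therefore always reported, and
the < 3 rule is applied at ≤ 2 by default (configurable). The simulation
in the test suite confirms the closed form within 3 standard errors.

Both the exhaustive sliding scan and a pigeonhole-seeded accelerator
(split the query into m+1 seeds; any hit within m mismatches matches one
seed exactly) are provided; tests assert identical hit sets. A TIR counts
once, at its minimum distance, regardless of how many positions match.

## Mismatch controls

Central mismatches are what abolish PNA activity, so negative controls
substitute positions symmetric about the oligomer centre (k=2 on an
11-mer: positions 5 and 7; the centre itself is used when k is odd; ties
break toward 5′). Each substitution is a transversion chosen so the new
base cannot pair with the target base at that position, including G:U
wobble (map A→C, C→A, G→T, T→G).

## Titers and effect categories

Titer = count × 10^d / volume, from the most dilute spot whose count lies
in the countable band, default 10–100 per 5 µl spot. The floor of 10 keeps
the relative Poisson error of the chosen spot ≤ ~32 % (1/√10); with a
floor of 3 the most-dilute-countable rule frequently selects counts of
3–8, whose ~0.15–0.25 log10 error is larger than the margin between
adjacent effect categories and makes sub-log effects (e.g. a planted
−1.2-log increase) unrecoverable at the advertised rates. If no spot falls
in the band, the most dilute numeric spot above it is used (counts up to
the lawn threshold remain quantifiable, only less precise). A fully blank
series is right-censored at the detection limit 10^d_min/volume; a series
whose only non-zero counts sit below the floor raises an explicit
ambiguity error.

Effect categories map Δ = log10(control) − log10(targeting) onto the
screen's ordinal scale: |Δ| < 1 → none; 1 ≤ Δ < 2 → "+"; 2 ≤ Δ < 4 →
"++"; Δ ≥ 4 (or a censored target with bound ≥ 4) → "+++"; Δ ≤ −1 → "−"
(titer increase). The labels come from the screen's reporting convention;
the numeric cut-offs (1/2/4 logs) are our calibration of "weak /
multiple logs / plaque elimination" and are fully configurable. A planted
Δ exactly on a boundary is intrinsically a coin flip under unbiased noise,
which is why recovery benchmarks plant effects at least 0.2 logs away from
the nearest boundary. Categorization uses PFU by default; CFU deltas are
computed alongside when present. Immunoblot-based scores are accepted as
external ordinal inputs, never computed.

## Temporal classification

A transcript is middle/late if log2FC > 2 with −log10(adjusted P) > 10,
early if log2FC < −2 at the same significance, else unclassified
(contrast: control condition, 35 vs 10 min post infection; positive =
higher at 35 min). The classifier consumes (log2FC, padj) pairs from any
differential-expression engine; no shrinkage or testing is re-implemented,
and the synthetic generator's naive draws are labelled non-equivalent to a
DESeq2 fit.

The knockdown-profile matrix drops genes missing from > 20 % of knockdown
tables and imputes the remainder as 0 (no change); dimensionality
reduction/clustering of that matrix is left to external tools, and tests
only verify that planted profile groups survive export (average-linkage
hierarchical clustering recovers them).

## Synthetic generators

`synth_genome` plants, per gene: an AGGAGG Shine–Dalgarno motif whose last
base sits at mRNA offset −8 (canonical aligned spacing), inside a −16..−1
initiation region whose sense strand is purine-biased at 0.6 (the A-rich
enhancer context of real bacterial TIRs), an ATG start, and random
background at configurable GC (default 0.5). Genes alternate strands and
never overlap. With unbiased flanks the antisense 11-mer over the SD would
be pyrimidine-poor purely by coin flip in ~19 % of genes; the 0.6 bias
makes the generator reflect the biological regularity the purine filter
exploits. The generator does **not** emulate real codon usage, operons,
overlapping genes, leaderless mRNAs or temporal expression — so passing
tests demonstrate correctness of the computations on TIR-like sequence
structure, not performance on any particular real genome.

`synth_screen_table` draws every spot count Poisson with mean
titer × volume × 10^−d over decade dilutions d = 0..8, control titer 10⁹
PFU/ml, and records counts > 300 as lawn-cleared. `synth_expression_table`
draws log2FC ~ N(±4 or 0, 0.75) per planted class and places −log10 padj
in (10.5, 14.5) for significant classes and (0, 9.5) otherwise; the ±4/0.75
defaults put the ±2 threshold ~2.7σ from the class means, matching the
clear separation of early vs late phage transcripts in time-course
RNA-seq.

## Percent identity

Global end-to-end alignment (BLOSUM62, affine gaps −11/−1, end gaps
penalized). Percent identity is reported under three denominators because
the convention is tool-dependent: all aligned columns (primary; gap
columns count against identity), non-gap columns only, and shorter
sequence length. For diverged homologue pairs these can differ by several
points, which is why the accession-anchored check carries a ±3-point
tolerance.

## Problem sizes

Test and acceptance runs use 5–20-gene synthetic genomes, a 370-TIR ×
200-query off-target null, 200 replicates per planted screen effect and
1000-gene expression tables — sizes at which the brute-force oracles the
suite compares against remain exact and the whole suite completes in
seconds, while every statistical assertion retains comfortable margins
(binomial SE at 200 replicates ≈ 1.5 percentage points).

## Known limitations

- No mismatch-duplex or secondary-structure thermodynamics; target-site
  accessibility is not modelled.
- Off-target scanning covers TIR windows (optionally whole TIR antisense),
  not full transcriptomes or proteome-level specificity.
- The ranking composite is declared, not learned; it encodes the stated
  filter plus sensible tie-breaks, and alternative weightings are easy to
  configure but not benchmarked.
- Effect categorization from spot counts inherits the coarseness of decade
  dilutions; effects smaller than ~0.5 log10 are not reliably callable.
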