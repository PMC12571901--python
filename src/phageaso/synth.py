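"""Seeded synthetic genomes, screen tables and expression tables.

Every generator is a pure function of its spec and seed, and returns a truth
table alongside the data so downstream calls can be scored without
re-deriving ground truth.  The genome generator emulates the layout of an
annotated phage genome: non-overlapping CDS on alternating strands, each
preceded by a 5' UTR carrying a planted Shine-Dalgarno motif (consensus
AGGAGG) at a canonical spacing from the AUG start codon, embedded in a
purine-biased initiation region as in real bacterial mRNAs.  It makes no
attempt to emulate real codon usage, operon structure or temporal programs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneModel, GenomeRecord, revcomp
from .screen import LAWN_CLEARED

__all__ = [
    "SynthSpec",
    "synth_genome",
    "random_tir_set",
    "synth_screen_table",
    "synth_expression_table",
    "CENSORED",
]

CENSORED = "censored"

_BASES = np.array(list("ACGT"))
_PURINES = np.array(list("AG"))
_PYRIMIDINES = np.array(list("CT"))


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic genome generator.

    ``sd_offset`` is the signed mRNA offset of the *last* base of the planted
    SD motif (default -8: motif ends 7 nt before the AUG, the canonical
    aligned spacing).  ``tir_purine_bias`` is the sense-strand purine
    probability in the -16..-1 initiation region outside the motif,
    emulating the A-rich enhancer context of real TIRs.
    """

    n_genes: int = 20
    gene_len_range: tuple[int, int] = (300, 900)
    sd_motif: str = "AGGAGG"
    sd_offset: int = -8
    gc_content: float = 0.5
    tir_purine_bias: float = 0.6
    utr_len: int = 30
    intergenic_range: tuple[int, int] = (60, 150)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.sd_offset >= 0:
            raise ValueError("sd_offset must be negative (motif is 5' of AUG)")
        if -self.sd_offset + len(self.sd_motif) - 1 > self.utr_len:
            raise ValueError("SD motif does not fit inside the UTR")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return list(rng.choice(_BASES, size=n, p=p))


def _utr(rng: np.random.Generator, spec: SynthSpec) -> str:
    """5' UTR (offsets -utr_len..-1) with the SD motif planted."""
    motif_hi = spec.sd_offset  # offset of last motif base
    motif_lo = spec.sd_offset - len(spec.sd_motif) + 1
    bases = []
    for off in range(-spec.utr_len, 0):
        if motif_lo <= off <= motif_hi:
            bases.append(spec.sd_motif[off - motif_lo])
        elif off >= -16:
            if rng.random() < spec.tir_purine_bias:
                bases.append(str(rng.choice(_PURINES)))
            else:
                bases.append(str(rng.choice(_PYRIMIDINES)))
        else:
            bases.append(_random_bases(rng, 1, spec.gc_content)[0])
    return "".join(bases)


def synth_genome(spec: SynthSpec) -> tuple[GenomeRecord, pd.DataFrame]:
    """Generate a genome with planted TIRs plus its truth table.

    Genes alternate strands and never overlap (each occupies its own block of
    intergenic spacer + UTR + CDS).  The truth table lists, per gene, the
    CDS coordinates, strand, planted UTR sequence (mRNA sense) and the mRNA
    offsets of the SD motif.
    """
    rng = np.random.default_rng(spec.seed)
    chunks: list[str] = []
    pos = 1  # next free 1-based coordinate
    genes: list[GeneModel] = []
    truth_rows = []
    for i in range(spec.n_genes):
        strand = "+" if i % 2 == 0 else "-"
        spacer = "".join(
            _random_bases(rng, int(rng.integers(*spec.intergenic_range)), spec.gc_content)
        )
        chunks.append(spacer)
        pos += len(spacer)
        utr = _utr(rng, spec)
        n_codons = int(rng.integers(*spec.gene_len_range)) // 3
        cds = "ATG" + "".join(_random_bases(rng, 3 * max(n_codons - 2, 1), spec.gc_content)) + "TAA"
        unit = utr + cds
        tag = f"SYN_{i + 1:04d}"
        if strand == "+":
            chunks.append(unit)
            start, end = pos + len(utr), pos + len(unit) - 1
        else:
            chunks.append(revcomp(unit))
            start, end = pos, pos + len(cds) - 1
        pos += len(unit)
        genes.append(GeneModel(locus_tag=tag, start=start, end=end, strand=strand))
        truth_rows.append(
            {
                "locus_tag": tag,
                "strand": strand,
                "start": start,
                "end": end,
                "utr_seq": utr,
                "cds_len": len(cds),
                "sd_motif": spec.sd_motif,
                "sd_from": spec.sd_offset - len(spec.sd_motif) + 1,
                "sd_to": spec.sd_offset,
            }
        )
    chunks.append(
        "".join(_random_bases(rng, int(rng.integers(*spec.intergenic_range)), spec.gc_content))
    )
    genome = GenomeRecord(
        id=f"SYNTH_{spec.seed}", sequence="".join(chunks), genes=genes
    )
    return genome, pd.DataFrame(truth_rows)


def random_tir_set(
    n_tirs: int,
    tir_len: int = 46,
    seed: int | np.random.Generator = 0,
    genome_id: str = "RANDTIR",
):
    """Uniform-random TIR windows for off-target null calibration.

    Sequences are i.i.d. uniform over ACGT (no planted structure); offsets
    are labelled -30..+(tir_len-30) purely for bookkeeping.
    """
    from .genome_io import TirWindow

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for i in range(n_tirs):
        seq = "".join(rng.choice(_BASES, size=tir_len))
        offs_to = tir_len - 30
        out.append(
            TirWindow(
                gene=f"RAND_{i + 1:04d}",
                seq=seq,
                offset_from=-30,
                offset_to=offs_to if offs_to != 0 else 1,
                genome_id=genome_id,
            )
        )
    return out


def synth_screen_table(
    true_deltas: Mapping[str, float | str],
    control_titer: float = 1e9,
    spot_volume_ul: float = 5.0,
    dilution_exponents: Sequence[int] = tuple(range(0, 9)),
    lawn_threshold: int = 300,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Poisson spot counts for planted log10 PFU effects.

    For each gene, the targeting-condition titer is
    ``control_titer * 10**(-delta)`` (``CENSORED`` plants a sterile series);
    every spot count is Poisson with mean titer * volume * 10^-d.  Counts
    above ``lawn_threshold`` are recorded as ``lawn-cleared``, as on a real
    plate.  Returns a long-format table (gene, aso_id, condition, assay,
    dilution_exponent, count).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vol_ml = spot_volume_ul * 1e-3
    rows = []
    for gene, delta in true_deltas.items():
        for condition in ("targeting", "control"):
            if condition == "control":
                titer = control_titer
            elif delta == CENSORED:
                titer = 0.0
            else:
                titer = control_titer * 10.0 ** (-float(delta))
            for d in dilution_exponents:
                lam = titer * vol_ml * 10.0**-d
                count = int(rng.poisson(lam)) if lam < 1e7 else int(lam)
                rows.append(
                    {
                        "gene": gene,
                        "aso_id": f"{gene}_aso1",
                        "condition": condition,
                        "assay": "PFU",
                        "dilution_exponent": d,
                        "count": LAWN_CLEARED if count > lawn_threshold else str(count),
                    }
                )
    return pd.DataFrame(rows)


def synth_expression_table(
    class_assignment: Mapping[str, str],
    lfc_means: Mapping[str, float] | None = None,
    noise_sd: float = 0.75,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Expression table (gene, log2fc, padj) with planted temporal classes.

    log2 fold changes are Normal(mean[class], noise_sd) with default means
    -4 (early), +4 (middle_late), 0 (unclassified); adjusted P values are
    drawn below the significance line (-log10 p in 10.5..14.5) for the two
    significant classes and above it (-log10 p in 0..9.5) for unclassified
    genes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    means = {"early": -4.0, "middle_late": 4.0, "unclassified": 0.0}
    if lfc_means:
        means.update(lfc_means)
    rows = []
    for gene, cls in class_assignment.items():
        if cls not in means:
            raise ValueError(f"{gene}: unknown class {cls!r}")
        log2fc = rng.normal(means[cls], noise_sd)
        if cls == "unclassified":
            neglog10p = rng.uniform(0.0, 9.5)
        else:
            neglog10p = rng.uniform(10.5, 14.5)
        rows.append({"gene": gene, "log2fc": log2fc, "padj": 10.0**-neglog10p})
    return pd.DataFrame(rows)
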