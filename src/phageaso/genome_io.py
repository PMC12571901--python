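"""Genome/annotation reading and translation-initiation-region (TIR) extraction.

Coordinates follow the GenBank/GFF3 convention: 1-based, inclusive, with the
``strand`` field giving the coding orientation.  mRNA offsets around the start
codon skip position 0: +1 is the A of the AUG (first base of the start codon)
and -1 the base immediately 5' of it, so a -30..+15 window spans 45 nt.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "GenomeRecord",
    "TirWindow",
    "GenomeParseError",
    "GenomeValidationError",
    "read_genome",
    "write_genome",
    "extract_tir",
    "extract_all_tirs",
    "write_tir_table",
    "read_tir_table",
    "revcomp",
    "mrna_offsets",
]

START_CODONS = ("ATG", "GTG", "TTG")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class GenomeParseError(ValueError):
    """Raised when an input genome or annotation file is malformed."""


class GenomeValidationError(ValueError):
    """Raised when parsed features violate basic genome invariants."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """One annotated feature, strand-aware, 1-based inclusive coordinates.

    For ``strand == '+'`` the start codon begins at ``start``; for
    ``strand == '-'`` it begins at ``end`` and reads inward (reverse
    complement convention).
    """

    locus_tag: str
    start: int
    end: int
    strand: str
    is_cds: bool = True
    name: str | None = None
    compound: bool = False  # joined/multi-part location; only first-part start used

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GenomeValidationError(
                f"{self.locus_tag}: start {self.start} > end {self.end}"
            )
        if self.strand not in "+-":
            raise GenomeValidationError(f"{self.locus_tag}: bad strand {self.strand!r}")


@dataclass
class GenomeRecord:
    """A named nucleotide sequence plus its gene models."""

    id: str
    sequence: str
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        if not self.sequence:
            raise GenomeValidationError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise GenomeValidationError(f"{self.id}: non-ACGTN bases {sorted(bad)}")
        for g in self.genes:
            if g.start < 1 or g.end > len(self.sequence):
                raise GenomeValidationError(
                    f"{g.locus_tag}: interval {g.start}..{g.end} outside "
                    f"1..{len(self.sequence)}"
                )

    @property
    def cds(self) -> list[GeneModel]:
        return [g for g in self.genes if g.is_cds]

    def get_gene(self, locus_tag: str, require_cds: bool = False) -> GeneModel:
        hits = [g for g in self.genes if g.locus_tag == locus_tag]
        if require_cds:
            hits = [g for g in hits if g.is_cds] or hits
        if not hits:
            raise KeyError(f"unknown locus_tag {locus_tag!r} in genome {self.id}")
        # prefer the CDS entry when a gene/CDS pair shares the tag
        for g in hits:
            if g.is_cds:
                return g
        return hits[0]


@dataclass(frozen=True)
class TirWindow:
    """mRNA-sense sequence around a start codon, in signed mRNA offsets.

    ``offset_from``/``offset_to`` use the zero-less mRNA coordinate system;
    ``seq`` is DNA alphabet (T, not U) read 5'->3' on the mRNA sense strand.
    """

    gene: str
    seq: str
    offset_from: int
    offset_to: int
    truncated: bool = False
    strand: str = "+"
    genome_id: str = ""

    def offsets(self) -> list[int]:
        """Signed mRNA offset of each base of ``seq``, in order."""
        return [o for o in range(self.offset_from, self.offset_to + 1) if o != 0]

    def has_start_codon(self) -> bool:
        offs = self.offsets()
        if 1 not in offs or 3 not in offs:
            return False
        i = offs.index(1)
        return self.seq[i : i + 3] in START_CODONS


def mrna_offsets(offset_from: int, offset_to: int) -> list[int]:
    """Enumerate the signed mRNA coordinates of a window (no position 0)."""
    if offset_from >= offset_to:
        raise ValueError(f"offset_from {offset_from} must be < offset_to {offset_to}")
    if offset_from == 0 or offset_to == 0:
        raise ValueError("mRNA coordinates have no position 0")
    return [o for o in range(offset_from, offset_to + 1) if o != 0]


# ---------------------------------------------------------------------------
# reading


def read_genome(
    path: str | os.PathLike,
    annotation: str | os.PathLike | None = None,
    fmt: str | None = None,
) -> GenomeRecord:
    """Read a genome from GenBank or FASTA+GFF3 into a :class:`GenomeRecord`.

    Parameters
    ----------
    path:
        GenBank flat file, or FASTA when ``annotation`` is given.
    annotation:
        GFF3 file with CDS features; its seqid must match the FASTA record id.
    fmt:
        ``"genbank"`` or ``"fasta+gff3"``; inferred from the file extension
        when omitted.

    One :class:`GeneModel` is produced per CDS feature; non-CDS features
    carrying a locus tag are retained with ``is_cds=False`` (``gene``
    features that merely mirror a CDS are dropped).  Joined/compound
    locations are flagged, with only the outermost span recorded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        if annotation is not None:
            fmt = "fasta+gff3"
        elif path.suffix.lower() in {".gb", ".gbk", ".gbff", ".genbank"}:
            fmt = "genbank"
        elif path.suffix.lower() in {".fa", ".fasta", ".fna"}:
            raise ValueError("FASTA input requires an annotation= GFF3 file")
        else:
            fmt = "genbank"
    if fmt == "genbank":
        return _read_genbank(path)
    if fmt == "fasta+gff3":
        if annotation is None:
            raise ValueError("fasta+gff3 format requires annotation=")
        return _read_fasta_gff3(path, Path(annotation))
    raise ValueError(f"unknown format {fmt!r}")


def _read_genbank(path: Path) -> GenomeRecord:
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise GenomeParseError(f"{path}: {exc}") from exc
    genes: list[GeneModel] = []
    cds_tags: set[str] = set()
    pending: list[GeneModel] = []
    for i, feat in enumerate(rec.features):
        if feat.type == "source":
            continue
        tag = _feature_tag(feat, default=f"{feat.type}_{i}")
        try:
            start = int(feat.location.start) + 1  # Biopython is 0-based half-open
            end = int(feat.location.end)
        except (TypeError, AttributeError) as exc:
            raise GenomeParseError(f"{path}: feature {i} ({tag}): bad location") from exc
        compound = len(feat.location.parts) > 1
        if compound:
            warnings.warn(
                f"{tag}: joined location; using outer span only", stacklevel=2
            )
        strand = "-" if feat.location.strand == -1 else "+"
        model = GeneModel(
            locus_tag=tag,
            start=start,
            end=end,
            strand=strand,
            is_cds=feat.type == "CDS",
            name=_first(feat.qualifiers.get("gene")),
            compound=compound,
        )
        if feat.type == "CDS":
            cds_tags.add(tag)
            genes.append(model)
        else:
            pending.append(model)
    # keep non-CDS features except entries shadowed by a CDS with the same tag
    genes.extend(m for m in pending if m.locus_tag not in cds_tags)
    return GenomeRecord(id=rec.id or path.stem, sequence=str(rec.seq), genes=genes)


def _first(values: Sequence[str] | None) -> str | None:
    return values[0] if values else None


def _feature_tag(feat, default: str) -> str:
    for key in ("locus_tag", "gene", "protein_id"):
        val = _first(feat.qualifiers.get(key))
        if val:
            return val
    return default


def _read_fasta_gff3(fasta_path: Path, gff_path: Path) -> GenomeRecord:
    import gffutils

    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise GenomeParseError(f"{fasta_path}: no FASTA records")
    if not gff_path.exists():
        raise FileNotFoundError(gff_path)
    try:
        db = gffutils.create_db(
            str(gff_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise GenomeParseError(f"{gff_path}: {exc}") from exc
    seqids = {r.id: str(r.seq) for r in records}
    feats = list(db.all_features())
    used_seqids = {f.seqid for f in feats}
    known = used_seqids & set(seqids)
    if feats and not known:
        raise GenomeParseError(
            f"{gff_path}: seqids {sorted(used_seqids)} not found in {fasta_path}"
        )
    if len(records) > 1 and len(known) == 1:
        rec_id = next(iter(known))
    else:
        rec_id = records[0].id
    genes: list[GeneModel] = []
    cds_tags: set[str] = set()
    for f in feats:
        if f.seqid != rec_id:
            continue
        tag = (
            _first(f.attributes.get("locus_tag"))
            or _first(f.attributes.get("ID"))
            or f.id
        )
        if f.featuretype == "region":
            continue
        model = GeneModel(
            locus_tag=tag,
            start=f.start,
            end=f.end,
            strand="-" if f.strand == "-" else "+",
            is_cds=f.featuretype == "CDS",
            name=_first(f.attributes.get("Name")) or _first(f.attributes.get("gene")),
        )
        if model.is_cds:
            cds_tags.add(tag)
            genes.append(model)
        elif not (model.locus_tag in cds_tags):
            genes.append(model)
    genes = [g for g in genes if g.is_cds or g.locus_tag not in cds_tags]
    return GenomeRecord(id=rec_id, sequence=seqids[rec_id], genes=genes)


# ---------------------------------------------------------------------------
# writing


def write_genome(genome: GenomeRecord, fasta_path: str | os.PathLike,
                 gff_path: str | os.PathLike) -> None:
    """Write a GenomeRecord as a FASTA file plus a GFF3 annotation."""
    fasta_path, gff_path = Path(fasta_path), Path(gff_path)
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome.id}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome.sequence)}\n")
        for g in genome.genes:
            ftype = "CDS" if g.is_cds else "gene"
            attrs = f"ID={g.locus_tag};locus_tag={g.locus_tag}"
            if g.name:
                attrs += f";Name={g.name}"
            fh.write(
                "\t".join(
                    [
                        genome.id,
                        "phageaso",
                        ftype,
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        "0" if g.is_cds else ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# TIR extraction


def extract_tir(
    genome: GenomeRecord,
    gene: str,
    offset_from: int = -30,
    offset_to: int = 15,
) -> TirWindow:
    """Extract the mRNA-sense TIR window of a CDS.

    The window is given in signed mRNA coordinates (no position 0; +1 = first
    base of the start codon).  Minus-strand genes are reverse complemented so
    ``seq`` always reads 5'->3' on the mRNA.  Bases falling off the contig are
    dropped and the window flagged ``truncated`` (genomes are treated as
    linear; no wrap-around).
    """
    model = genome.get_gene(gene, require_cds=True)
    if not model.is_cds:
        raise ValueError(f"{gene}: not a CDS feature")
    offs = mrna_offsets(offset_from, offset_to)
    anchor = model.start if model.strand == "+" else model.end
    L = len(genome.sequence)
    kept_offs: list[int] = []
    bases: list[str] = []
    for o in offs:
        step = o - 1 if o > 0 else o
        pos = anchor + step if model.strand == "+" else anchor - step
        if pos < 1 or pos > L:
            continue
        kept_offs.append(o)
        base = genome.sequence[pos - 1]
        bases.append(base if model.strand == "+" else base.translate(_COMPLEMENT))
    if not kept_offs:
        raise ValueError(f"{gene}: window {offset_from}..{offset_to} lies entirely off-contig")
    truncated = len(kept_offs) != len(offs)
    if truncated:
        warnings.warn(
            f"{gene}: TIR window clipped at contig edge "
            f"({offset_from}..{offset_to} -> {kept_offs[0]}..{kept_offs[-1]})",
            stacklevel=2,
        )
    return TirWindow(
        gene=gene,
        seq="".join(bases),
        offset_from=kept_offs[0],
        offset_to=kept_offs[-1],
        truncated=truncated,
        strand=model.strand,
        genome_id=genome.id,
    )


def extract_all_tirs(
    genome: GenomeRecord,
    offset_from: int = -30,
    offset_to: int = 15,
    genes: Iterable[str] | None = None,
) -> list[TirWindow]:
    """TIR windows for every CDS (or a subset of locus tags)."""
    tags = list(genes) if genes is not None else [g.locus_tag for g in genome.cds]
    return [extract_tir(genome, t, offset_from, offset_to) for t in tags]


def write_tir_table(tirs: Sequence[TirWindow], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {
            "gene": [t.gene for t in tirs],
            "genome": [t.genome_id for t in tirs],
            "strand": [t.strand for t in tirs],
            "offset_from": [t.offset_from for t in tirs],
            "offset_to": [t.offset_to for t in tirs],
            "seq": [t.seq for t in tirs],
            "truncated": [t.truncated for t in tirs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_tir_table(path: str | os.PathLike) -> list[TirWindow]:
    df = pd.read_csv(path, sep="\t")
    return [
        TirWindow(
            gene=str(r.gene),
            seq=str(r.seq),
            offset_from=int(r.offset_from),
            offset_to=int(r.offset_to),
            truncated=bool(r.truncated),
            strand=str(r.strand),
            genome_id="" if pd.isna(r.genome) else str(r.genome),
        )
        for r in df.itertuples()
    ]
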