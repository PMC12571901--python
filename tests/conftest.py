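"""Shared fixtures: small synthetic genomes and annotation files."""

from __future__ import annotations

import pytest

from phageaso import GeneModel, GenomeRecord, SynthSpec, synth_genome

# Printed control oligomer used across tests (non-targeting control PNA).
CONTROL_ASO = "GACATAATTGT"


@pytest.fixture(scope="session")
def small_genome():
    """Deterministic 6-gene synthetic genome plus its truth table."""
    return synth_genome(SynthSpec(n_genes=6, seed=11))


@pytest.fixture(scope="session")
def design_genome():
    """20-gene genome used for design-pipeline oracle checks."""
    genome, truth = synth_genome(SynthSpec(n_genes=20, seed=1))
    return genome, truth


@pytest.fixture()
def plus_gene_genome():
    """Hand-built genome with one + strand CDS and known TIR context.

    The -20..+6 window of the gene reads GACAACATAAAGGATTTAAAATGAAT with the
    ATG start codon at offsets +1..+3.
    """
    context = "GACAACATAAAGGATTTAAAATGAAT"
    pad5 = "CGTACGTACGTACGTACGTA"  # 20 nt
    pad3 = "GGCCTTAAGGCCTTAAGGCC"
    seq = pad5 + context + pad3
    start = len(pad5) + context.index("ATG", 18) + 1  # 1-based ATG position
    gene = GeneModel(locus_tag="gene1", start=start, end=len(seq) - len(pad3), strand="+")
    return GenomeRecord(id="TOY", sequence=seq, genes=[gene]), context


def make_genbank(tmp_path, genome: GenomeRecord):
    """Write a GenomeRecord as a GenBank flat file (via Biopython)."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                    description="synthetic fixture")
    rec.annotations["molecule_type"] = "DNA"
    for g in genome.genes:
        loc = FeatureLocation(g.start - 1, g.end, strand=1 if g.strand == "+" else -1)
        feat = SeqFeature(loc, type="CDS" if g.is_cds else "gene")
        feat.qualifiers["locus_tag"] = [g.locus_tag]
        rec.features.append(feat)
    path = tmp_path / f"{genome.id}.gb"
    from Bio import SeqIO

    SeqIO.write(rec, str(path), "genbank")
    return path
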