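"""Antisense oligomer (ASO/PNA) candidate enumeration, scoring and selection.

Candidates are 11-mers (configurable) antisense to the translation-initiation
region of a target gene.  Each is scored for predicted PNA/DNA melting
temperature, purine fraction and self-complementarity, profiled for
mismatch-tolerant off-targets across all phage (and optionally host) TIRs,
then filtered and ranked.  The design filter mirrors the criteria used for
RBS-targeting PNA screens: Tm 45-55 C, purine fraction 25-35%, fewer than 3
off-target TIRs, low self-complementarity, and at least two passing ASOs per
gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from . import thermo
from .genome_io import GenomeRecord, TirWindow, extract_all_tirs, extract_tir, revcomp
from .offtarget import OffTargetProfile, count_offtarget_tirs

__all__ = [
    "AsoCandidate",
    "DesignConfig",
    "enumerate_candidates",
    "purine_fraction",
    "self_complementarity",
    "score_candidates",
    "apply_filters",
    "tile_window",
    "make_mismatch_control",
    "design_asos",
    "candidates_to_frame",
]

# Central-mismatch substitution map: each base to a transversion that cannot
# pair (Watson-Crick or G:U wobble) with the original target base.
_MISMATCH_SUB = {"A": "C", "C": "A", "G": "T", "T": "G"}


@dataclass
class AsoCandidate:
    """One candidate antisense oligomer against a TIR site.

    ``aso_seq`` is the reverse complement of ``target_site_seq``, written
    5'->3' in DNA alphabet; the PNA N-terminus corresponds to the 5' end.
    ``site_from``/``site_to`` are signed mRNA offsets (no position 0).
    """

    gene: str
    target_site_seq: str
    site_from: int
    site_to: int
    aso_seq: str
    centre_offset: int = 0
    tm_c: float | None = None
    purine_frac: float | None = None
    selfcomp: int | None = None
    has_n: bool = False
    offtargets: OffTargetProfile | None = None
    passes: bool | None = None
    rank: int | None = None
    fail_reasons: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return len(self.aso_seq)

    def offtarget_cumulative(self, mm: int) -> int | None:
        if self.offtargets is None:
            return None
        return int(self.offtargets.cumulative_by_mm[mm])


@dataclass(frozen=True)
class DesignConfig:
    """All tunables of the design filter, with screen-style defaults."""

    length: int = 11
    window_from: int = -30
    window_to: int = 15
    tm_min: float = 45.0
    tm_max: float = 55.0
    purine_min: float = 0.25
    purine_max: float = 0.35
    max_offtarget_tirs: int = 3  # criterion is "< max"
    offtarget_criterion_mm: int = 2  # mismatch level where the < rule applies
    report_mm: int = 4
    selfcomp_max: int = 5
    min_asos_per_gene: int = 2
    tm_model: thermo.TmModel = field(default_factory=lambda: thermo.DEFAULT_TM_MODEL)

    def __post_init__(self) -> None:
        if not self.tm_min < self.tm_max:
            raise ValueError("tm_min must be < tm_max")
        if not self.purine_min < self.purine_max:
            raise ValueError("purine_min must be < purine_max")
        if self.offtarget_criterion_mm > self.report_mm:
            raise ValueError("offtarget_criterion_mm must be <= report_mm")

    @property
    def tm_mid(self) -> float:
        return 0.5 * (self.tm_min + self.tm_max)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DesignConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        tm_model = raw.pop("tm_model", None)
        cfg = cls(**raw)
        if tm_model:
            cfg = replace(cfg, tm_model=thermo.TmModel(**tm_model))
        return cfg


def purine_fraction(seq: str) -> float:
    """Fraction of purines (A+G) in a DNA sequence."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT bases {sorted(bad)}")
    return (seq.count("A") + seq.count("G")) / len(seq)


def self_complementarity(seq: str) -> int:
    """Length of the longest substring whose reverse complement also occurs in seq.

    Exhaustive scan over all substrings (overlap allowed).  A homopolymer has
    self-complementarity 0; a full palindrome scores its own length.
    """
    seq = seq.upper()
    if len(seq) < 2:
        raise ValueError("need length >= 2")
    n = len(seq)
    best = 0
    for size in range(n, 0, -1):
        for i in range(n - size + 1):
            if revcomp(seq[i : i + size]) in seq:
                return size
    return best


def enumerate_candidates(tir: TirWindow, length: int = 11) -> list[AsoCandidate]:
    """One unscored candidate per start position of the TIR window."""
    if length < 6:
        raise ValueError("ASO length must be >= 6")
    offs = tir.offsets()
    L = len(tir.seq)
    if length > L:
        warnings.warn(
            f"{tir.gene}: window ({L} nt) shorter than ASO length {length}; "
            "no candidates",
            stacklevel=2,
        )
        return []
    out = []
    for i in range(L - length + 1):
        site = tir.seq[i : i + length]
        out.append(
            AsoCandidate(
                gene=tir.gene,
                target_site_seq=site,
                site_from=offs[i],
                site_to=offs[i + length - 1],
                aso_seq=revcomp(site),
                centre_offset=offs[i + length // 2],
                has_n="N" in site,
            )
        )
    return out


def score_candidates(
    candidates: Iterable[AsoCandidate],
    config: DesignConfig = DesignConfig(),
) -> list[AsoCandidate]:
    """Attach Tm, purine fraction and self-complementarity scores in place."""
    out = list(candidates)
    for c in out:
        if c.has_n:
            continue  # degenerate bases: left unscored, excluded by the filter
        c.tm_c = thermo.pna_tm(c.aso_seq, config.tm_model)
        c.purine_frac = purine_fraction(c.aso_seq)
        c.selfcomp = self_complementarity(c.aso_seq)
    return out


def _filter_verdict(c: AsoCandidate, config: DesignConfig) -> tuple[bool, tuple[str, ...]]:
    reasons = []
    if c.has_n:
        reasons.append("contains_N")
        return False, tuple(reasons)
    if c.tm_c is None or c.purine_frac is None or c.selfcomp is None:
        reasons.append("unscored")
        return False, tuple(reasons)
    if not (config.tm_min <= c.tm_c <= config.tm_max):
        reasons.append("tm")
    if not (config.purine_min <= c.purine_frac <= config.purine_max):
        reasons.append("purine")
    if c.selfcomp > config.selfcomp_max:
        reasons.append("selfcomp")
    ot = c.offtarget_cumulative(config.offtarget_criterion_mm)
    if ot is None:
        reasons.append("no_offtarget_profile")
    elif ot >= config.max_offtarget_tirs:
        reasons.append("offtargets")
    return not reasons, tuple(reasons)


def _rank_key(c: AsoCandidate, config: DesignConfig):
    ot = c.offtarget_cumulative(config.offtarget_criterion_mm)
    return (
        ot if ot is not None else 10**9,
        abs((c.tm_c if c.tm_c is not None else 1e9) - config.tm_mid),
        abs(c.centre_offset),
        c.site_from,
    )


def apply_filters(
    candidates: Sequence[AsoCandidate],
    config: DesignConfig = DesignConfig(),
) -> list[AsoCandidate]:
    """Set pass/fail on every candidate and return them ranked.

    A candidate passes iff Tm, purine fraction and self-complementarity fall
    within the configured bounds and the number of distinct off-target TIRs
    at <= ``offtarget_criterion_mm`` mismatches (target excluded) is below
    ``max_offtarget_tirs``.  Ranking is deterministic: fewest off-targets,
    then |Tm - band midpoint|, then site centre closest to the start codon,
    then 5'-most site; passing candidates precede failing ones.  Genes with
    fewer than ``min_asos_per_gene`` passing candidates are reported by
    :func:`design_asos` as under-designed.
    """
    out = list(candidates)
    for c in out:
        c.passes, c.fail_reasons = _filter_verdict(c, config)
    out.sort(key=lambda c: (not c.passes, _rank_key(c, config)))
    for i, c in enumerate(out, start=1):
        c.rank = i
    return out


def tile_window(
    genome: GenomeRecord,
    gene: str,
    offset_from: int = -37,
    offset_to: int = 44,
    length: int = 11,
    config: DesignConfig = DesignConfig(),
) -> list[AsoCandidate]:
    """Fully scored tiling of a widened TIR window, with no filtering.

    Used for empirical tiling experiments (default window -37..+44 around the
    start codon, i.e. 81 positions and 71 11-mer candidates when the window
    is not truncated); each candidate is annotated with its site centre
    offset.
    """
    tir = extract_tir(genome, gene, offset_from, offset_to)
    return score_candidates(enumerate_candidates(tir, length), config)


def make_mismatch_control(aso: AsoCandidate | str, k: int) -> str:
    """A control sequence at Hamming distance exactly k, mismatches central.

    Substituted positions are placed symmetrically about the centre of the
    oligomer (for k=2 on an 11-mer: positions 5 and 7 of 1..11), the centre
    position itself being used when k is odd; remaining ties break toward
    the 5' end.  Each substitution is a transversion that cannot pair with
    the target base at that position (no Watson-Crick or G:U wobble pair).
    """
    seq = aso.aso_seq if isinstance(aso, AsoCandidate) else str(aso).upper()
    L = len(seq)
    if not 1 <= k <= L - 2:
        raise ValueError(f"k must be in 1..{L - 2}, got {k}")
    centre = (L + 1) // 2 if L % 2 else L // 2  # 1-based; ties toward 5'
    positions: list[int] = []
    if k % 2:
        positions.append(centre)
    offset = 1
    while len(positions) < k:
        left, right = centre - offset, centre + offset
        if left >= 1:
            positions.append(left)
        if len(positions) < k and right <= L:
            positions.append(right)
        offset += 1
    bases = list(seq)
    for p in sorted(positions[:k]):
        bases[p - 1] = _MISMATCH_SUB[bases[p - 1]]
    return "".join(bases)


def design_asos(
    genome: GenomeRecord,
    genes: Iterable[str] | None = None,
    host: GenomeRecord | None = None,
    config: DesignConfig = DesignConfig(),
) -> pd.DataFrame:
    """End-to-end design: TIRs -> candidates -> scores -> off-targets -> ranking.

    Off-targets are counted over the TIRs of the phage and, when supplied, of
    the host genome (reported separately and combined).  Returns one row per
    candidate; genes whose passing candidates number fewer than
    ``config.min_asos_per_gene`` are flagged ``under_designed``.
    """
    tags = list(genes) if genes is not None else [g.locus_tag for g in genome.cds]
    tir_sets: list[tuple[str, list[TirWindow]]] = [
        (genome.id, extract_all_tirs(genome, config.window_from, config.window_to))
    ]
    if host is not None:
        tir_sets.append(
            (host.id, extract_all_tirs(host, config.window_from, config.window_to))
        )
    frames = []
    for tag in tags:
        tir = extract_tir(genome, tag, config.window_from, config.window_to)
        cands = score_candidates(enumerate_candidates(tir, config.length), config)
        for c in cands:
            c.offtargets = count_offtarget_tirs(
                c.target_site_seq, c.gene, tir_sets, report_mm=config.report_mm
            )
        cands = apply_filters(cands, config)
        n_pass = sum(bool(c.passes) for c in cands)
        if n_pass < config.min_asos_per_gene:
            warnings.warn(
                f"{tag}: only {n_pass} passing candidate(s); gene is under-designed",
                stacklevel=2,
            )
        df = candidates_to_frame(cands, report_mm=config.report_mm)
        df["under_designed"] = n_pass < config.min_asos_per_gene
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def candidates_to_frame(
    candidates: Sequence[AsoCandidate], report_mm: int = 4
) -> pd.DataFrame:
    """Tabulate candidates; byte-stable for identical inputs and config."""
    rows = []
    for c in candidates:
        row = {
            "gene": c.gene,
            "site_from": c.site_from,
            "site_to": c.site_to,
            "centre_offset": c.centre_offset,
            "target_site_seq": c.target_site_seq,
            "aso_seq": c.aso_seq,
            "tm_c": c.tm_c,
            "purine_frac": None if c.purine_frac is None else round(c.purine_frac, 4),
            "selfcomp": c.selfcomp,
            "passes": c.passes,
            "rank": c.rank,
            "fail_reasons": ",".join(c.fail_reasons),
        }
        for m in range(report_mm + 1):
            if c.offtargets is not None:
                row[f"ot_mm{m}"] = int(c.offtargets.counts_by_mm[m])
                row[f"cum_mm{m}"] = int(c.offtargets.cumulative_by_mm[m])
            else:
                row[f"ot_mm{m}"] = None
                row[f"cum_mm{m}"] = None
        rows.append(row)
    return pd.DataFrame(rows)
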