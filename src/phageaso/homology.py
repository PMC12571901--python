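"""Pairwise global protein alignment and percent identity.

Percent identity is convention-sensitive; the primary figure reported here
uses *all aligned columns* (gap columns count in the denominator), with the
two common alternatives (ungapped columns only; shorter sequence length)
reported alongside.  Scoring defaults to BLOSUM62 with affine gaps
(open -11, extend -1), end gaps penalized (true global alignment).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = ["AlignParams", "IdentityResult", "percent_identity"]

_AA = set("ACDEFGHIKLMNPQRSTVWYX")  # X allowed, always scored as mismatch


@dataclass(frozen=True)
class AlignParams:
    matrix: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class IdentityResult:
    """Percent identity of one global alignment, under several denominators."""

    pid: float  # identical / aligned columns (gaps in denominator)
    aligned_len: int
    identical: int
    gaps: int
    pid_ungapped: float  # identical / non-gap columns
    pid_shorter: float  # identical / length of the shorter sequence
    score: float


def _validate(seq: str, label: str) -> str:
    seq = seq.upper().strip("*")
    if not seq:
        raise ValueError(f"{label}: empty protein sequence")
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"{label}: non-amino-acid characters {sorted(bad)}")
    return seq


def percent_identity(
    seq_a: str, seq_b: str, params: AlignParams = AlignParams()
) -> IdentityResult:
    """Global (end-to-end) percent identity of two protein sequences."""
    a = _validate(seq_a, "seq_a")
    b = _validate(seq_b, "seq_b")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    aln = aligner.align(a, b)[0]
    col_a, col_b = str(aln[0]), str(aln[1])
    aligned_len = len(col_a)
    identical = sum(x == y and x != "-" for x, y in zip(col_a, col_b))
    gaps = sum(x == "-" or y == "-" for x, y in zip(col_a, col_b))
    ungapped = aligned_len - gaps
    return IdentityResult(
        pid=100.0 * identical / aligned_len,
        aligned_len=aligned_len,
        identical=identical,
        gaps=gaps,
        pid_ungapped=100.0 * identical / ungapped if ungapped else 0.0,
        pid_shorter=100.0 * identical / min(len(a), len(b)),
        score=float(aln.score),
    )
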