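"""Mismatch-tolerant off-target counting over translation-initiation regions.

The search is an ungapped Hamming scan of each candidate's target-site
sequence (mRNA sense, DNA alphabet) over every TIR of the phage and,
optionally, the host.  A TIR is counted once, at its minimum distance over
all alignment positions ("distinct-TIR counting"), and the candidate's own
gene is excluded.  Counts at exactly 0..report_mm mismatches and their
cumulative form are both reported; the design filter applies the "< max
off-target TIRs" rule at a configurable mismatch level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_io import TirWindow, revcomp

__all__ = [
    "OffTargetHit",
    "OffTargetProfile",
    "hamming_sites",
    "hamming_sites_seeded",
    "min_hamming_distance",
    "count_offtarget_tirs",
    "expected_random_tir_hits",
]


@dataclass(frozen=True)
class OffTargetHit:
    """One mismatch-tolerant occurrence of a query inside a subject TIR.

    ``position`` is the 1-based start of the match within the subject string.
    """

    subject_gene: str
    subject_genome: str
    position: int
    mismatches: int


@dataclass
class OffTargetProfile:
    """Distinct-TIR off-target counts for one query, stratified by mismatch level.

    ``per_genome[g][m]`` counts TIRs of genome ``g`` whose minimum Hamming
    distance to the query is exactly ``m``; the target gene's own TIR is
    excluded everywhere.
    """

    query_gene: str
    report_mm: int
    per_genome: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def counts_by_mm(self) -> np.ndarray:
        """Combined exact-distance counts over all genomes, index = mismatches."""
        total = np.zeros(self.report_mm + 1, dtype=int)
        for counts in self.per_genome.values():
            total += counts
        return total

    @property
    def cumulative_by_mm(self) -> np.ndarray:
        """Combined distinct-TIR counts at <= m mismatches."""
        return np.cumsum(self.counts_by_mm)

    def cumulative_for(self, genome_id: str) -> np.ndarray:
        return np.cumsum(self.per_genome[genome_id])


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _window_distances(query: str, subject: str) -> np.ndarray:
    """Hamming distance of the query to every length-|query| window of subject."""
    q = _encode(query)
    s = _encode(subject)
    if len(q) > len(s):
        return np.zeros(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(s, len(q))
    return (windows != q).sum(axis=1)


def hamming_sites(
    query: str,
    subject: str,
    max_mm: int,
    subject_gene: str = "",
    subject_genome: str = "",
) -> list[OffTargetHit]:
    """All ungapped occurrences of ``query`` in ``subject`` within ``max_mm``.

    Computed by exhaustive sliding comparison; this is the reference path
    that the pigeonhole-seeded accelerator must reproduce exactly.
    """
    dists = _window_distances(query.upper(), subject.upper())
    return [
        OffTargetHit(subject_gene, subject_genome, pos + 1, int(d))
        for pos, d in enumerate(dists)
        if d <= max_mm
    ]


def hamming_sites_seeded(
    query: str,
    subject: str,
    max_mm: int,
    subject_gene: str = "",
    subject_genome: str = "",
) -> list[OffTargetHit]:
    """Pigeonhole-seeded Hamming search; identical hit set to :func:`hamming_sites`.

    The query is split into ``max_mm + 1`` contiguous seeds; any window within
    ``max_mm`` mismatches must match at least one seed exactly, so candidate
    positions are collected from exact seed occurrences and then verified.
    """
    query, subject = query.upper(), subject.upper()
    L, n = len(query), len(subject)
    if L > n:
        return []
    k = max_mm + 1
    bounds = [round(i * L / k) for i in range(k + 1)]
    candidates: set[int] = set()
    for i in range(k):
        lo, hi = bounds[i], bounds[i + 1]
        seed = query[lo:hi]
        if not seed:
            continue
        start = subject.find(seed)
        while start != -1:
            qstart = start - lo
            if 0 <= qstart <= n - L:
                candidates.add(qstart)
            start = subject.find(seed, start + 1)
    hits = []
    for pos in sorted(candidates):
        d = sum(a != b for a, b in zip(query, subject[pos : pos + L]))
        if d <= max_mm:
            hits.append(OffTargetHit(subject_gene, subject_genome, pos + 1, d))
    return hits


def min_hamming_distance(query: str, subject: str) -> int:
    """Minimum ungapped Hamming distance of query over all subject windows."""
    dists = _window_distances(query.upper(), subject.upper())
    if dists.size == 0:
        return len(query)  # query longer than subject: nothing alignable
    return int(dists.min())


def count_offtarget_tirs(
    target_site_seq: str,
    query_gene: str | None,
    tir_sets: Sequence[tuple[str, Sequence[TirWindow]]] | Mapping[str, Sequence[TirWindow]],
    report_mm: int = 4,
    scan_antisense: bool = False,
) -> OffTargetProfile:
    """Distinct-TIR off-target profile of one target-site sequence.

    Parameters
    ----------
    target_site_seq:
        The candidate's mRNA-sense target site (the search is defined on the
        sense sequence; scanning the reverse-complemented ASO against TIR
        antisense strands is equivalent).
    query_gene:
        Locus tag of the intended target; its TIR(s) are excluded.  ``None``
        declares a null-model scan with no intended target (no warning).
    tir_sets:
        ``(genome_id, [TirWindow, ...])`` pairs (phage first, host optional).
    report_mm:
        Maximum mismatch level reported (counts at exactly 0..report_mm).
    scan_antisense:
        Also scan the reverse complement of each TIR (off by default: an ASO
        binds mRNA, which exists only in sense orientation).
    """
    if isinstance(tir_sets, Mapping):
        tir_sets = list(tir_sets.items())
    query = target_site_seq.upper()
    profile = OffTargetProfile(query_gene=query_gene or "", report_mm=report_mm)
    target_seen = False
    for genome_id, tirs in tir_sets:
        counts = np.zeros(report_mm + 1, dtype=int)
        for tir in tirs:
            if query_gene is not None and tir.gene == query_gene:
                target_seen = True
                continue
            d = min_hamming_distance(query, tir.seq)
            if scan_antisense:
                d = min(d, min_hamming_distance(query, revcomp(tir.seq)))
            if d <= report_mm:
                counts[d] += 1
        profile.per_genome[genome_id] = counts
    if query_gene is not None and not target_seen:
        warnings.warn(
            f"target gene {query_gene!r} not present in any TIR set; "
            "no self-exclusion performed",
            stacklevel=2,
        )
    return profile


def expected_random_tir_hits(
    n_tirs: int, tir_len: int, query_len: int, max_mm: int
) -> float:
    """Closed-form expected number of random TIRs within ``max_mm`` mismatches.

    Under a uniform-base null, a fixed query matches one random site within
    m mismatches with probability p = sum_{k<=m} C(L,k) 3^k / 4^L; a TIR of
    length W offers W - L + 1 sites, so the expected distinct-TIR count is
    n * (1 - (1 - p)^(W - L + 1)).  Positions within a TIR overlap and are
    not independent, but at the small p involved the approximation error is
    far below sampling noise.
    """
    p = sum(math.comb(query_len, k) * 3**k for k in range(max_mm + 1)) / 4**query_len
    sites = tir_len - query_len + 1
    if sites <= 0:
        return 0.0
    return n_tirs * (1.0 - (1.0 - p) ** sites)
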