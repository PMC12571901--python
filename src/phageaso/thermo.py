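"""Duplex melting temperature for PNA antisense oligomers.

The predictor is the standard two-step model used by RBS-targeting ASO design
tools: (1) the DNA/DNA duplex melting temperature of the oligomer against its
perfect complement from a nearest-neighbor (NN) free-energy sum, and (2) a
linear PNA/DNA correction

    Tm_PNA = b0 + b1 * Tm_NN + b2 * f_pyr + b3 * L

where ``f_pyr`` is the pyrimidine fraction of the PNA strand and ``L`` its
length in bases.  Default coefficients are the published PNA/DNA regression
(20.79, 0.83, -26.13, 0.44); the NN table is the unified duplex parameter set
(SantaLucia-type, 1 M Na+, no salt correction) evaluated at 4 uM total strand
concentration.  Everything is held in :class:`TmModel` so an alternative
parameterization can be swapped in wholesale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .genome_io import revcomp

__all__ = ["TmModel", "DEFAULT_TM_MODEL", "nn_tm", "pna_tm", "melting_temperature"]

R_GAS = 1.987  # cal / (mol K)

# Unified DNA/DNA NN parameters: dinucleotide (5'->3' on one strand) ->
# (dH kcal/mol, dS cal/mol/K).  Dinucleotides absent here are looked up via
# their reverse complement (duplex symmetry).
UNIFIED_NN: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}

# Duplex initiation terms, by terminal base pair.
INIT_GC = (0.1, -2.8)
INIT_AT = (2.3, 4.1)


@dataclass(frozen=True)
class TmModel:
    """Versioned parameter block for the PNA Tm predictor."""

    nn_table: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(UNIFIED_NN)
    )
    init_gc: tuple[float, float] = INIT_GC
    init_at: tuple[float, float] = INIT_AT
    total_strand_conc_m: float = 4e-6  # total duplex strand concentration (mol/l)
    beta0: float = 20.79
    beta1: float = 0.83
    beta2: float = -26.13  # times pyrimidine fraction of the PNA strand
    beta3: float = 0.44  # times oligomer length
    version: str = "unified-NN/PNA-linear-1.0"


DEFAULT_TM_MODEL = TmModel()


def _check_acgt(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"sequence contains non-ACGT bases {sorted(bad)}")
    if len(seq) < 2:
        raise ValueError("need at least a dinucleotide")
    return seq


def nn_tm(seq: str, model: TmModel = DEFAULT_TM_MODEL) -> float:
    """DNA/DNA duplex Tm (deg C) of ``seq`` against its perfect complement.

    Non-self-complementary duplex assumed: Tm = dH / (dS + R ln(C_T/4)).
    """
    seq = _check_acgt(seq)
    dh, ds = 0.0, 0.0
    for term in (seq[0], seq[-1]):
        h, s = model.init_gc if term in "GC" else model.init_at
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        dinuc = seq[i : i + 2]
        pair = model.nn_table.get(dinuc) or model.nn_table.get(revcomp(dinuc))
        if pair is None:
            raise ValueError(f"no NN parameters for {dinuc!r}")
        dh += pair[0]
        ds += pair[1]
    tm_k = (dh * 1000.0) / (ds + R_GAS * math.log(model.total_strand_conc_m / 4.0))
    return tm_k - 273.15


def pyrimidine_fraction(seq: str) -> float:
    seq = _check_acgt(seq)
    return (seq.count("C") + seq.count("T")) / len(seq)


def pna_tm(aso_seq: str, model: TmModel = DEFAULT_TM_MODEL) -> float:
    """Predicted PNA/DNA duplex Tm (deg C) for a PNA of sequence ``aso_seq``."""
    aso_seq = _check_acgt(aso_seq)
    tm = (
        model.beta0
        + model.beta1 * nn_tm(aso_seq, model)
        + model.beta2 * pyrimidine_fraction(aso_seq)
        + model.beta3 * len(aso_seq)
    )
    return round(tm, 1)


def melting_temperature(
    aso_seq: str,
    target_site_seq: str | None = None,
    model: TmModel = DEFAULT_TM_MODEL,
) -> float:
    """PNA/DNA Tm of an ASO against its target site, reported to 0.1 deg C.

    ``target_site_seq``, when given, must be the exact reverse complement of
    ``aso_seq`` (mismatched-duplex thermodynamics are out of scope).
    """
    aso_seq = _check_acgt(aso_seq)
    if target_site_seq is not None:
        target = _check_acgt(target_site_seq)
        if revcomp(aso_seq) != target:
            raise ValueError("target_site_seq is not the reverse complement of aso_seq")
    return pna_tm(aso_seq, model)
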