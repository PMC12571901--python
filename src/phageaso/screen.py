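"""Knockdown-screen read-outs: titers, effect categories, temporal classes.

Serial-dilution spot counts (5 ul spots, decade dilutions) are turned into
CFU/PFU titers; targeting-vs-control titer deltas are mapped onto the
screen's ordinal effect categories (none, +, ++, +++, -); and per-gene
differential-expression records (log2 fold change 35 vs 10 min after
infection, adjusted P) are classified as early vs middle/late transcripts.

Countable range: a spot is used for titration only when its count lies in
10..100 (configurable).  Below ~10 the relative Poisson error of a single
spot exceeds ~32%, which is too noisy to support the one-log category
boundaries; above ~100 plaques/colonies merge.  The most dilute countable
spot is used, matching standard plaque-assay practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpotCount",
    "ScreenRecord",
    "Titer",
    "EffectThresholds",
    "EffectCall",
    "ExpressionRecord",
    "AmbiguousTiterError",
    "titer_from_spots",
    "effect_category",
    "classify_temporal",
    "classify_expression_table",
    "knockdown_profile_matrix",
    "read_spot_table",
    "screen_effect_table",
    "LAWN_CLEARED",
    "BELOW_DETECTION",
]

LAWN_CLEARED = "lawn-cleared"  # confluent lysis / uncountably many
BELOW_DETECTION = "below-detection"

CATEGORIES = ("-", "none", "+", "++", "+++")


class AmbiguousTiterError(ValueError):
    """No countable spot and no censoring signal: titer cannot be computed."""


@dataclass(frozen=True)
class SpotCount:
    """One spot: dilution exponent d (a 10^-d dilution) and its count.

    ``count`` is an int, or one of the sentinels ``LAWN_CLEARED`` (too many
    to count) / ``BELOW_DETECTION`` (nothing visible).
    """

    dilution_exponent: int
    count: int | str

    def __post_init__(self) -> None:
        if isinstance(self.count, str):
            if self.count not in (LAWN_CLEARED, BELOW_DETECTION):
                raise ValueError(f"bad count sentinel {self.count!r}")
        elif self.count < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class ScreenRecord:
    """Spot counts at serial dilutions for one (gene, ASO, condition, assay)."""

    gene: str
    aso_id: str
    condition: str  # {"targeting", "control"}
    assay: str  # {"CFU", "PFU"}
    spots: list[SpotCount] = field(default_factory=list)
    spot_volume_ul: float = 5.0

    def __post_init__(self) -> None:
        self.spots = [
            s if isinstance(s, SpotCount) else SpotCount(*s) for s in self.spots
        ]
        exps = [s.dilution_exponent for s in self.spots]
        if any(b <= a for a, b in zip(exps, exps[1:])):
            raise ValueError("dilution exponents must be strictly increasing")


@dataclass(frozen=True)
class Titer:
    """A titer in units/ml; ``censored`` marks an upper bound at the detection limit."""

    value: float
    censored: bool = False

    @property
    def log10(self) -> float:
        return math.log10(self.value)


def titer_from_spots(
    record: ScreenRecord,
    countable_min: int = 10,
    countable_max: int = 100,
) -> Titer:
    """Titer (per ml) from the most dilute countable spot of a serial dilution.

    titer = count * 10^d / (spot volume in ml).  When no spot falls in the
    preferred band the most dilute numeric spot above it is used instead
    (counts up to the lawn threshold are still quantifiable, only less
    precise).  When every spot is zero or below detection the titer is
    right-censored at the detection limit 1/volume * 10^d_min.  A series
    whose only non-zero counts sit below the quantification floor is
    ambiguous and raises.
    """
    if not record.spots:
        raise AmbiguousTiterError(f"{record.gene}/{record.aso_id}: no spots")
    vol_ml = record.spot_volume_ul * 1e-3
    countable = [
        s
        for s in record.spots
        if isinstance(s.count, int) and countable_min <= s.count <= countable_max
    ]
    if countable:
        best = max(countable, key=lambda s: s.dilution_exponent)
        return Titer(best.count * 10.0**best.dilution_exponent / vol_ml)
    overshoot = [
        s for s in record.spots if isinstance(s.count, int) and s.count > countable_max
    ]
    if overshoot:
        best = max(overshoot, key=lambda s: s.dilution_exponent)
        return Titer(best.count * 10.0**best.dilution_exponent / vol_ml)
    all_blank = all(
        (isinstance(s.count, int) and s.count == 0) or s.count == BELOW_DETECTION
        for s in record.spots
    )
    if all_blank:
        d_min = min(s.dilution_exponent for s in record.spots)
        return Titer(10.0**d_min / vol_ml, censored=True)
    raise AmbiguousTiterError(
        f"{record.gene}/{record.aso_id}: no spot in the countable range "
        f"{countable_min}..{countable_max} and series is not below detection"
    )


@dataclass(frozen=True)
class EffectThresholds:
    """log10 titer-reduction cut-offs for the ordinal effect categories."""

    weak: float = 1.0  # "+"  : one log
    effective: float = 2.0  # "++" : two logs ("multiple logs")
    very: float = 4.0  # "+++": four logs or plaque elimination

    def __post_init__(self) -> None:
        if not 0 < self.weak < self.effective < self.very:
            raise ValueError("thresholds must satisfy 0 < weak < effective < very")


@dataclass(frozen=True)
class EffectCall:
    """Categorized effect of one knockdown: Δ = log10(control) − log10(target)."""

    gene: str
    delta_log10: float
    category: str
    censored: bool = False
    assay: str = "PFU"


def effect_category(
    target: Titer,
    control: Titer,
    thresholds: EffectThresholds = EffectThresholds(),
    gene: str = "",
    assay: str = "PFU",
) -> EffectCall:
    """Map a targeting-vs-control titer pair onto an ordinal effect category.

    Δ = log10(control) − log10(target).  Defaults: |Δ| < 1 → "none";
    1 ≤ Δ < 2 → "+"; 2 ≤ Δ < 4 → "++"; Δ ≥ 4 → "+++"; Δ ≤ −1 → "−"
    (titer increase).  A right-censored target titer makes Δ a lower bound;
    the category is assigned from that bound and the call flagged censored.
    """
    delta = control.log10 - target.log10
    if delta <= -thresholds.weak:
        cat = "-"
    elif delta < thresholds.weak:
        cat = "none"
    elif delta < thresholds.effective:
        cat = "+"
    elif delta < thresholds.very:
        cat = "++"
    else:
        cat = "+++"
    return EffectCall(
        gene=gene,
        delta_log10=delta,
        category=cat,
        censored=target.censored or control.censored,
        assay=assay,
    )


# ---------------------------------------------------------------------------
# temporal classification


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene differential expression between 35 and 10 min post infection."""

    gene: str
    log2fc: float
    padj: float

    def __post_init__(self) -> None:
        if not 0.0 < self.padj <= 1.0:
            raise ValueError(f"{self.gene}: padj must be in (0, 1], got {self.padj}")


def classify_temporal(
    record: ExpressionRecord | None = None,
    *,
    log2fc: float | None = None,
    padj: float | None = None,
    lfc_threshold: float = 2.0,
    neglog10p_threshold: float = 10.0,
) -> str:
    """Early vs middle/late transcript class from one (log2fc, padj) pair.

    The contrast is control condition 35 min vs 10 min post infection
    (positive log2fc = higher at 35 min).  middle_late: log2fc > 2 and
    −log10(padj) > 10; early: log2fc < −2 and −log10(padj) > 10; everything
    else is unclassified.
    """
    if record is not None:
        log2fc, padj = record.log2fc, record.padj
    if log2fc is None or padj is None:
        raise ValueError("need an ExpressionRecord or log2fc= and padj=")
    if not 0.0 < padj <= 1.0:
        raise ValueError(f"padj must be in (0, 1], got {padj}")
    significant = -math.log10(padj) > neglog10p_threshold
    if significant and log2fc > lfc_threshold:
        return "middle_late"
    if significant and log2fc < -lfc_threshold:
        return "early"
    return "unclassified"


def classify_expression_table(
    df: pd.DataFrame,
    lfc_threshold: float = 2.0,
    neglog10p_threshold: float = 10.0,
) -> pd.DataFrame:
    """Vectorized :func:`classify_temporal` over a (gene, log2fc, padj) table."""
    if (df["padj"] <= 0).any() or (df["padj"] > 1).any():
        raise ValueError("padj must be in (0, 1]")
    out = df.copy()
    sig = -np.log10(out["padj"]) > neglog10p_threshold
    out["class"] = "unclassified"
    out.loc[sig & (out["log2fc"] > lfc_threshold), "class"] = "middle_late"
    out.loc[sig & (out["log2fc"] < -lfc_threshold), "class"] = "early"
    return out


def knockdown_profile_matrix(
    tables: Mapping[str, pd.DataFrame],
    max_missing_frac: float = 0.2,
) -> pd.DataFrame:
    """Gene x knockdown matrix of log2 fold changes for external clustering.

    Genes missing from more than ``max_missing_frac`` of the knockdown tables
    are dropped; remaining missing entries are imputed as 0 (no change).
    Raises when no gene is shared by every table.
    """
    if not tables:
        raise ValueError("no tables supplied")
    cols = {}
    for name, df in tables.items():
        cols[name] = df.set_index("gene")["log2fc"]
    mat = pd.DataFrame(cols)
    shared = mat.dropna(how="any")
    if shared.empty:
        raise ValueError("no gene is present in every knockdown table")
    keep = mat.isna().mean(axis=1) <= max_missing_frac
    mat = mat.loc[keep].fillna(0.0)
    return mat.sort_index()


# ---------------------------------------------------------------------------
# table IO


def read_spot_table(path: str | Path, spot_volume_ul: float = 5.0) -> list[ScreenRecord]:
    """Read a spot-count TSV (gene, aso_id, condition, assay, dilution_exponent, count)."""
    df = pd.read_csv(path, sep="\t", dtype={"count": str})
    return spot_table_to_records(df, spot_volume_ul=spot_volume_ul)


def spot_table_to_records(
    df: pd.DataFrame, spot_volume_ul: float = 5.0
) -> list[ScreenRecord]:
    records = []
    keys = ["gene", "aso_id", "condition", "assay"]
    for (gene, aso_id, condition, assay), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("dilution_exponent")
        spots = []
        for _, row in grp.iterrows():
            raw = str(row["count"])
            count: int | str = raw if raw in (LAWN_CLEARED, BELOW_DETECTION) else int(raw)
            spots.append(SpotCount(int(row["dilution_exponent"]), count))
        records.append(
            ScreenRecord(
                gene=gene,
                aso_id=aso_id,
                condition=condition,
                assay=assay,
                spots=spots,
                spot_volume_ul=spot_volume_ul,
            )
        )
    return records


def screen_effect_table(
    records: Sequence[ScreenRecord],
    thresholds: EffectThresholds = EffectThresholds(),
    countable_min: int = 10,
    countable_max: int = 100,
) -> pd.DataFrame:
    """Per (gene, aso_id, assay) effect calls from paired targeting/control records."""
    by_key: dict[tuple[str, str, str], dict[str, ScreenRecord]] = {}
    for rec in records:
        by_key.setdefault((rec.gene, rec.aso_id, rec.assay), {})[rec.condition] = rec
    rows = []
    for (gene, aso_id, assay), pair in sorted(by_key.items()):
        if "targeting" not in pair or "control" not in pair:
            continue
        target = titer_from_spots(pair["targeting"], countable_min, countable_max)
        control = titer_from_spots(pair["control"], countable_min, countable_max)
        call = effect_category(target, control, thresholds, gene=gene, assay=assay)
        rows.append(
            {
                "gene": gene,
                "aso_id": aso_id,
                "assay": assay,
                "target_titer": target.value,
                "target_censored": target.censored,
                "control_titer": control.value,
                "delta_log10": round(call.delta_log10, 4),
                "category": call.category,
                "censored": call.censored,
            }
        )
    return pd.DataFrame(rows)
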