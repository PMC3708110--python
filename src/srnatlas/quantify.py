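"""Expression reporting: reads-per-million normalization and qPCR fold levels.

RPM (reads per million mapped) is ``count / denominator * 1e6``.  The
default denominator is the total number of miRNA-mapped reads, which is
what makes per-miRNA RPM values sum to one million; the alternative
``all_mapped`` mode divides by every annotated mapped read.  RT-qPCR
relative expression follows the standard ``2^-dCt`` form with
``dCt = Ct(target) - Ct(reference)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd

__all__ = [
    "ExpressionRecord",
    "QPCRMeasurement",
    "rpm_table",
    "library_fraction",
    "relative_expression",
    "implied_denominator",
    "load_published_expression",
]


@dataclass(frozen=True)
class ExpressionRecord:
    name: str
    total_reads: int
    rpm: float


@dataclass(frozen=True)
class QPCRMeasurement:
    target_name: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{self.target_name}: cycle values must be positive finite")


def rpm_table(
    counts: Mapping[str, int],
    denominator_mode: str = "mirna_mapped",
    all_mapped_total: int | None = None,
) -> list[ExpressionRecord]:
    """Per-miRNA RPM records, sorted by descending RPM (stable).

    ``mirna_mapped`` divides by the sum of the given counts; ``all_mapped``
    requires ``all_mapped_total``.
    """
    if denominator_mode == "mirna_mapped":
        denom = sum(counts.values())
    elif denominator_mode == "all_mapped":
        if not all_mapped_total:
            raise ValueError("all_mapped mode needs all_mapped_total")
        denom = all_mapped_total
    else:
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    if denom <= 0:
        raise ValueError("RPM denominator must be positive")
    recs = [
        ExpressionRecord(name, c, round(c / denom * 1e6, 1))
        for name, c in counts.items()
    ]
    recs.sort(key=lambda r: (-r.rpm, r.name))
    return recs


def library_fraction(count: int, mapped_total: int) -> float:
    """Percent of the mapped library contributed by one feature."""
    if mapped_total <= 0:
        raise ValueError("mapped_total must be positive")
    return 100.0 * count / mapped_total


def relative_expression(m: QPCRMeasurement) -> float:
    """2^-dCt with dCt = Ct(target) - Ct(reference)."""
    return 2.0 ** -(m.ct_target - m.ct_reference)


def implied_denominator(counts_and_rpm: list[tuple[int, float]]) -> tuple[float, float]:
    """Back out the per-million denominator from printed (count, RPM) pairs.

    Returns the mean implied denominator and its coefficient of variation
    across rows; a published RPM table computed from a single denominator
    has CV ~ rounding noise.
    """
    denoms = [c / rpm * 1e6 for c, rpm in counts_and_rpm if rpm > 0]
    mean = sum(denoms) / len(denoms)
    var = sum((d - mean) ** 2 for d in denoms) / len(denoms)
    return mean, math.sqrt(var) / mean


def consistent_denominator(
    counts_and_rpm: list[tuple[int, float]], precision: float = 0.05
) -> int:
    """Smallest integer denominator reproducing every printed RPM to precision.

    Each printed (count, RPM) row constrains the denominator to the interval
    ``[count*1e6/(rpm+precision), count*1e6/(rpm-precision)]``; a table
    computed from a single mapped-read total has a non-empty intersection.
    """
    lo, hi = 0.0, float("inf")
    for c, rpm in counts_and_rpm:
        if rpm <= 0:
            continue
        lo = max(lo, c * 1e6 / (rpm + precision))
        hi = min(hi, c * 1e6 / (rpm - precision))
    if lo > hi:
        raise ValueError("no single denominator reproduces all printed RPM values")
    return math.ceil(lo)


def expression_frame(records: list[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"name": r.name, "total_reads": r.total_reads, "rpm": r.rpm} for r in records]
    )


def load_published_expression() -> pd.DataFrame:
    """Published miRNA expression table for the bovine retinal-endothelial
    small RNA library (miRBase v16 names; reads and reads-per-million-mapped).

    Used as a desk-check input for the RPM arithmetic and as the abundance
    skew the synthetic generator emulates.
    """
    path = resources.files("srnatlas.data") / "bovine_rmec_mirna_expression.tsv"
    return pd.read_csv(path, sep="\t")
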