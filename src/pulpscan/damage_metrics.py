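"""Damage rate from pre/post cavity areas, and per-deformation summaries.

The damage rate of one fruit is

    A = (S2 - S1) / S1 * 100   [%]

with S1 the cavity pixel area before compression and S2 after.  A may be
negative (cavity shrinkage is reported, not clamped).  Group summaries give
the mean and sample standard deviation of A per deformation level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def damage_rate(S1: float, S2: float) -> float:
    """Percent change of cavity area from pre- (S1) to post-compression (S2).

    Scale-free: only the ratio S2/S1 matters, so pixel areas need no
    physical calibration.
    """
    if S1 <= 0:
        raise ValueError(f"pre-compression cavity area must be positive, got {S1}")
    if S2 < 0:
        raise ValueError(f"post-compression cavity area must be non-negative, got {S2}")
    return (S2 - S1) / S1 * 100.0


@dataclass(frozen=True)
class DamageRecord:
    """One fruit's pre/post cavity areas and damage rate."""

    sample_id: str
    deformation_mm: float
    S1: float
    S2: float
    A: float

    @classmethod
    def from_areas(cls, sample_id, deformation_mm, S1, S2) -> "DamageRecord":
        return cls(str(sample_id), float(deformation_mm), float(S1), float(S2),
                   damage_rate(S1, S2))

    def __post_init__(self) -> None:
        if self.S1 <= 0:
            raise ValueError("S1 must be positive")
        expected = damage_rate(self.S1, self.S2)
        if not np.isclose(self.A, expected, rtol=0, atol=1e-9):
            raise ValueError(f"A={self.A} inconsistent with areas (expected {expected})")


@dataclass(frozen=True)
class GroupDamageSummary:
    """Mean and sample SD of damage rate at one deformation level."""

    deformation_mm: float
    n: int
    mean_A: float
    sd_A: float
    sd_defined: bool = True  # False for single-record groups

    def table_row(self) -> str:
        """Two-decimal display row, matching the usual group-table format."""
        return f"{self.deformation_mm:g}\t{self.mean_A:.2f} ± {self.sd_A:.2f}\t{self.n}"


def summarize_group(records, deformation_mm: float) -> GroupDamageSummary:
    """Mean and sample (n-1) SD of A over the records at one deformation."""
    rates = [r.A for r in records if r.deformation_mm == deformation_mm]
    if not rates:
        raise ValueError(f"no records at deformation {deformation_mm} mm")
    n = len(rates)
    mean = float(np.mean(rates))
    if n == 1:
        return GroupDamageSummary(float(deformation_mm), 1, mean, 0.0, sd_defined=False)
    sd = float(np.std(rates, ddof=1))
    return GroupDamageSummary(float(deformation_mm), n, mean, sd)


def summarize_all(records) -> list[GroupDamageSummary]:
    """One summary per deformation level present, in increasing order."""
    levels = sorted({r.deformation_mm for r in records})
    return [summarize_group(records, lv) for lv in levels]
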