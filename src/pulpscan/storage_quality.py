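"""Storage-experiment metrics: respiration rate, decay rate, change vs control.

Respiration rate of sealed fruit follows

    rate = (C1 - C2) * V / (m * t)    [mL CO2 kg^-1 h^-1]

where C1 and C2 are the CO2 volume fractions in the sealed box with and
without fruit, V the container volume (mL), m the fruit mass (kg) and t the
sealing time (h).  Decay rate is the percent of fruits in a group with
visible mold symptoms; by protocol it is scored on a dedicated subgroup of
20 fruits, so ``group_size`` defaults to 20.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

DEFAULT_DECAY_GROUP_SIZE = 20


@dataclass(frozen=True)
class StorageObservation:
    """One group's quality measurements on one storage day."""

    group: float  # deformation level, mm (0 = control)
    day: int
    firmness: float | None = None
    respiration: float | None = None  # mL kg^-1 h^-1
    tss: float | None = None  # % soluble solids
    ta: float | None = None  # % citric acid
    decayed_count: int | None = None
    group_size: int = DEFAULT_DECAY_GROUP_SIZE

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError("storage day must be non-negative")
        if self.decayed_count is not None and not (
            0 <= self.decayed_count <= self.group_size
        ):
            raise ValueError("decayed_count must lie in [0, group_size]")


@dataclass(frozen=True)
class RespirationInput:
    """Inputs of the sealed-box CO2 respiration measurement."""

    C1: float  # CO2 volume fraction, box with sample
    C2: float  # CO2 volume fraction, empty box
    V: float  # container volume, mL
    m: float  # fruit mass, kg
    t: float  # sealing time, h

    def __post_init__(self) -> None:
        if self.V <= 0 or self.m <= 0 or self.t <= 0:
            raise ValueError("V, m and t must all be positive")
        if self.C1 < 0 or self.C2 < 0:
            raise ValueError("CO2 concentrations must be non-negative")


def respiration_rate(inp: RespirationInput) -> float:
    """(C1 - C2) * V / (m * t); negative values flag a suspect measurement.

    The result is linear in the concentration difference and inversely
    proportional to fruit mass and sealing time.
    """
    return (inp.C1 - inp.C2) * inp.V / (inp.m * inp.t)


def decay_rate(decayed_count: int, group_size: int = DEFAULT_DECAY_GROUP_SIZE) -> float:
    """Percent of fruits in the group with visible decay symptoms."""
    if group_size <= 0:
        raise ValueError("group_size must be positive")
    if not (0 <= decayed_count <= group_size):
        raise ValueError("decayed_count must lie in [0, group_size]")
    return 100.0 * decayed_count / group_size


def percent_change_vs_control(treated: float, control: float) -> float:
    """Percent by which ``treated`` is *lower* than ``control``.

    Positive means lower than the control (the usual direction for quality
    indices that mechanical damage depresses); negative means higher.
    """
    if control == 0:
        raise ValueError("control value must be nonzero")
    return 100.0 * (control - treated) / control


def load_observations(path) -> pd.DataFrame:
    """Read a StorageObservation-schema CSV into a validated DataFrame."""
    df = pd.read_csv(path)
    required = {"group", "day"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"storage table missing columns: {sorted(missing)}")
    if (df["day"] < 0).any():
        raise ValueError("storage day must be non-negative")
    if "decayed_count" in df.columns:
        size = df["group_size"] if "group_size" in df.columns else DEFAULT_DECAY_GROUP_SIZE
        bad = (df["decayed_count"] < 0) | (df["decayed_count"] > size)
        if bad.fillna(False).any():
            raise ValueError("decayed_count outside [0, group_size]")
    return df


def decay_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-group, per-day decay rates from a storage observation table."""
    if "decayed_count" not in df.columns:
        raise ValueError("no decayed_count column in storage table")
    out = df.dropna(subset=["decayed_count"]).copy()
    size = out["group_size"] if "group_size" in out.columns else DEFAULT_DECAY_GROUP_SIZE
    out["decay_rate_pct"] = 100.0 * out["decayed_count"] / size
    return out[["group", "day", "decayed_count", "decay_rate_pct"]]
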