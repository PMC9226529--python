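"""Editing efficiency from electrophoresis band measurements.

A band's molar abundance is proportional to its signal (greyscale from a
gel image, or peak area from a capillary trace) divided by its length in
bp. Editing efficiency is the edited band's share of the length-normalised
signal:

    efficiency = 100 * (S_e / L_e) / (S_e / L_e + S_n / L_n)

The same formula serves both signal kinds; the measurement's ``role``
records which band it is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

ROLES = ("edited", "non_edited")


@dataclass(frozen=True)
class BandMeasurement:
    """One band: role, signal (arbitrary units, >= 0) and length (bp > 0)."""

    role: str
    signal: float
    length: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.signal < 0:
            raise ValueError("band signal must be non-negative")
        if self.length <= 0:
            raise ValueError("band length must be positive")


def efficiency(
    edited: BandMeasurement, non_edited: BandMeasurement
) -> float | None:
    """Editing efficiency in percent, or ``None`` when both signals are
    zero (undefined)."""
    if edited.signal == 0 and non_edited.signal == 0:
        return None
    dens_e = edited.signal / edited.length
    dens_n = non_edited.signal / non_edited.length
    return 100.0 * dens_e / (dens_e + dens_n)


def efficiency_table(lanes: pd.DataFrame | Iterable[dict]) -> pd.DataFrame:
    """Batch efficiencies from a table with columns ``lane`` (optional),
    ``role``, ``signal``, ``length`` — one edited and one non_edited row
    per lane."""
    df = pd.DataFrame(lanes)
    if "lane" not in df.columns:
        df = df.assign(lane=0)
    rows = []
    for lane, grp in df.groupby("lane", sort=True):
        bands = {
            row["role"]: BandMeasurement(row["role"], row["signal"], row["length"])
            for _, row in grp.iterrows()
        }
        missing = set(ROLES) - set(bands)
        if missing:
            raise ValueError(f"lane {lane!r} missing band role(s): {sorted(missing)}")
        eff = efficiency(bands["edited"], bands["non_edited"])
        rows.append(
            {
                "lane": lane,
                "efficiency_pct": eff,
                "efficiency_pct_rounded": None if eff is None else round(eff, 1),
            }
        )
    return pd.DataFrame(rows)
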