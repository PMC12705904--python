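"""Tooth morphometry arithmetic: maturity index, instrumented canal
volume, and extent of instrumentation.

The maturity index MI = mean apical root thickness / mean apical canal
width (measured at 0.25, 0.5, 0.75 and 1.0 mm from the foramen) proxies
root developmental maturity; teeth are grouped by the integer floor of
MI. The instrumented canal volume follows from the Archimedes mass
difference of two impressions, and the extent of instrumentation is the
mean radial depth of dentine removed per quadrant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd


@dataclass
class ToothMorphometry:
    """Raw per-tooth measurements.

    rt, cw: root thickness and canal width (mm) at four apical levels;
    mass_v1, mass_v2: impression masses (g) before/after instrumentation;
    density: impression material density (g/cm^3);
    ei: extent-of-instrumentation distances (mm), one per quadrant.
    """

    rt: list[float]
    cw: list[float]
    mass_v1: float = 0.0
    mass_v2: float = 0.0
    density: float = 1.0
    ei: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rt or not self.cw:
            raise ValueError("rt and cw measurements are required")
        if any(v <= 0 for v in self.rt + self.cw):
            raise ValueError("rt and cw measurements must be > 0")
        if self.mass_v2 < self.mass_v1:
            raise ValueError("mass_v2 must be >= mass_v1")
        if any(v < 0 for v in self.ei):
            raise ValueError("extent-of-instrumentation distances must be >= 0")


def maturity_index(m: ToothMorphometry) -> tuple[float, int]:
    """MI = mean(rt)/mean(cw) and its integer-floor maturity group."""
    mi = (sum(m.rt) / len(m.rt)) / (sum(m.cw) / len(m.cw))
    return mi, int(math.floor(mi))


def instrumented_volume(m: ToothMorphometry) -> float:
    """Instrumented canal volume in cm^3: (mass_v2 - mass_v1) / density."""
    if m.density <= 0:
        raise ValueError("density must be > 0")
    return (m.mass_v2 - m.mass_v1) / m.density


def mean_extent_instrumentation(m: ToothMorphometry) -> float:
    """Mean of the per-quadrant instrumentation distances (mm)."""
    if not m.ei:
        raise ValueError("no extent-of-instrumentation measurements")
    if len(m.ei) < 4:
        warnings.warn(
            f"only {len(m.ei)} quadrant(s) supplied; mean taken over those"
        )
    return sum(m.ei) / len(m.ei)


def derive_morphometry_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add derived columns to a morphometry table (one row per tooth).

    Expects columns rt1..rt4, cw1..cw4, mass_v1, mass_v2, density and
    ei1..ei4; adds mi, maturity_group, vol_instrumented_cm3, ei_mean_mm.
    """
    out = df.copy()
    records = []
    for _, row in df.iterrows():
        m = ToothMorphometry(
            rt=[row[f"rt{i}"] for i in range(1, 5)],
            cw=[row[f"cw{i}"] for i in range(1, 5)],
            mass_v1=row.get("mass_v1", 0.0),
            mass_v2=row.get("mass_v2", 0.0),
            density=row.get("density", 1.0),
            ei=[row[f"ei{i}"] for i in range(1, 5) if f"ei{i}" in row],
        )
        mi, group = maturity_index(m)
        records.append(
            {
                "mi": mi,
                "maturity_group": group,
                "vol_instrumented_cm3": instrumented_volume(m),
                "ei_mean_mm": mean_extent_instrumentation(m) if m.ei else float("nan"),
            }
        )
    derived = pd.DataFrame(records, index=df.index)
    return pd.concat([out, derived], axis=1)
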