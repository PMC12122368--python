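"""Cost extrapolation for broad-scale reef restoration.

Published per-hectare restoration costs span roughly US$6,000 to
US$143 million depending on technique and setting (Bayraktarov et al.
2016, PLoS ONE).  Total cost is linear in rehabilitated area, so the
arithmetic is simple but the magnitudes are the point: restoring 10% of
the ~11,700 km^2 of reef degraded over 2009-2018 means 117,000 ha,
which at the upper bound costs ~US$16.7 trillion.

The bundled per-technique cost table
(``data/synthetic_cost_schemes.csv``) is a synthetic stand-in anchored
to those published grand bounds and to the coral-gardening headline
total; it is editable package data, not an authoritative cost survey.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

HA_PER_KM2 = 100.0


@dataclass
class CostScheme:
    """Per-hectare cost bounds (US$) for one restoration technique."""

    technique: str
    low: float
    median: float
    high: float

    def __post_init__(self):
        if not (0 < self.low <= self.median <= self.high):
            raise ValueError("cost bounds must satisfy 0 < low <= median <= high")


def load_cost_schemes() -> dict[str, CostScheme]:
    """Bundled synthetic stand-in per-technique cost table."""
    ref = importlib.resources.files("reefrestore.data") / "synthetic_cost_schemes.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return {row["technique"]: CostScheme(row["technique"], row["low_usd_per_ha"],
                                         row["median_usd_per_ha"],
                                         row["high_usd_per_ha"])
            for _, row in df.iterrows()}


def read_cost_schemes(path) -> dict[str, CostScheme]:
    df = pd.read_csv(path)
    return {row["technique"]: CostScheme(row["technique"], row["low_usd_per_ha"],
                                         row["median_usd_per_ha"],
                                         row["high_usd_per_ha"])
            for _, row in df.iterrows()}


def cost_curve(scheme: CostScheme, areas_ha) -> pd.DataFrame:
    """Low/median/high total cost (US$) at each area; linear through origin."""
    areas = np.atleast_1d(np.asarray(areas_ha, dtype=float))
    if np.any(areas < 0):
        raise ValueError("areas must be >= 0")
    return pd.DataFrame({
        "area_ha": areas,
        "low_usd": scheme.low * areas,
        "median_usd": scheme.median * areas,
        "high_usd": scheme.high * areas,
    })


def area_for_fraction(total_area_km2: float, fraction: float) -> float:
    """Hectares in ``fraction`` of a km^2 area (1 km^2 = 100 ha)."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    if total_area_km2 < 0:
        raise ValueError("area must be >= 0")
    return total_area_km2 * fraction * HA_PER_KM2


def taxonomic_coverage(records: pd.DataFrame,
                       localities: pd.DataFrame) -> float:
    """Mean percent of local coral richness used across records.

    Per record: genera used / local species richness; records at
    localities with zero (or missing) richness are excluded.  Returned
    as a percentage.
    """
    rich = localities.set_index("id")["coral_richness"]
    ratios = []
    for _, r in records.iterrows():
        richness = rich.get(r["locality_id"], np.nan)
        if pd.isna(richness) or richness <= 0:
            continue
        ratios.append(float(r["n_genera"]) / float(richness))
    if not ratios:
        raise ValueError("no records with positive local richness")
    return float(np.mean(ratios) * 100.0)
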