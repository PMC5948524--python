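"""Fruit-damage indices and harvesting-efficiency summaries.

Colour index: CI = L* x (b* - a*) x 10^-2 from CIELAB coordinates measured
on the fruit skin — positive for green-yellow fruit, dropping as tones turn
brownish.  Bruising incidence: a severity-weighted mean over the bruise
categories non-bruised (weight 0), low damage (<25% of skin, weight 1) and
severe (25-100%, weight 2), so BI runs from 0 (no bruising) to 2 (all
severe).  Harvest efficiency combines row time per hectare, fruit removal
percentage and the percentage of fruit dropped to the ground (scaled up
from a sampling frame).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: ground-loss sampling frame, 2.5 m x 2.5 m
DEFAULT_GROUND_SAMPLE_AREA = 6.25

__all__ = [
    "FruitColour",
    "BruiseCounts",
    "HarvestPlot",
    "EfficiencySummary",
    "colour_index",
    "bruising_incidence",
    "harvest_efficiency",
    "colour_index_table",
]


@dataclass(frozen=True)
class FruitColour:
    """CIELAB colour triple measured on the fruit skin."""

    L_star: float
    a_star: float
    b_star: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.L_star <= 100.0:
            raise ValueError("L* must lie in [0, 100]")


@dataclass(frozen=True)
class BruiseCounts:
    """Counts per bruising category: none / low (<25% skin) / severe."""

    n0: int
    nl: int
    ns: int

    def __post_init__(self) -> None:
        if min(self.n0, self.nl, self.ns) < 0:
            raise ValueError("category counts must be non-negative")
        if self.n0 + self.nl + self.ns == 0:
            raise ValueError("at least one fruit must be counted")


@dataclass(frozen=True)
class HarvestPlot:
    """Per-row harvest bookkeeping for efficiency metrics."""

    row_time_h: float
    row_area_ha: float
    total_yield_kg: float
    fruit_left_on_tree_kg: float
    ground_sample_weight_kg: float
    ground_sample_area_m2: float = DEFAULT_GROUND_SAMPLE_AREA

    def __post_init__(self) -> None:
        if self.row_area_ha <= 0 or self.ground_sample_area_m2 <= 0:
            raise ValueError("areas must be positive")
        for name in ("row_time_h", "total_yield_kg", "fruit_left_on_tree_kg",
                     "ground_sample_weight_kg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class EfficiencySummary:
    time_per_ha: float       # h/ha
    removal_pct: float       # % of total production detached from the trees
    ground_loss_pct: float   # % of total production dropped to the ground


def colour_index(colour: FruitColour) -> float:
    """CI = L* x (b* - a*) x 10^-2."""
    return colour.L_star * (colour.b_star - colour.a_star) * 1e-2


def colour_index_table(df: pd.DataFrame) -> pd.Series:
    """Vectorised colour index for a table with L_star/a_star/b_star columns."""
    for col in ("L_star", "a_star", "b_star"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    return df["L_star"] * (df["b_star"] - df["a_star"]) * 1e-2


def bruising_incidence(counts: BruiseCounts) -> float:
    """BI = (0*N0 + 1*NL + 2*NS) / (N0 + NL + NS), in [0, 2]."""
    total = counts.n0 + counts.nl + counts.ns
    return (counts.nl + 2 * counts.ns) / total


def harvest_efficiency(plot: HarvestPlot,
                       ground_sample_area: float | None = None,
                       ) -> EfficiencySummary:
    """Time per hectare, fruit removal %, and ground loss %.

    Removal % is the detached share of total production.  The ground loss
    extrapolates the sampling-frame weight linearly to the harvested row
    footprint (1 ha = 10,000 m^2) and expresses it relative to total
    production; the removal and ground figures therefore share a
    denominator, and removal% + left-on-tree% = 100 exactly.
    """
    area = plot.ground_sample_area_m2 if ground_sample_area is None else ground_sample_area
    if area <= 0:
        raise ValueError("ground sample area must be positive")
    if plot.total_yield_kg <= 0:
        raise ValueError("total yield is zero: removal percentage undefined")
    time_per_ha = plot.row_time_h / plot.row_area_ha
    removal = 100.0 * (plot.total_yield_kg - plot.fruit_left_on_tree_kg) / plot.total_yield_kg
    ground_total = plot.ground_sample_weight_kg * (plot.row_area_ha * 1e4 / area)
    ground_pct = 100.0 * ground_total / plot.total_yield_kg
    return EfficiencySummary(time_per_ha=time_per_ha, removal_pct=removal,
                             ground_loss_pct=ground_pct)
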