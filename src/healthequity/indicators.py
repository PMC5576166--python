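"""Density indicators on two bases, settlement classification, group summaries,
and WHO workforce-threshold checks.

Two indicators are computed per resource: counts per 10 000 population
(per-capita equity) and counts per 1 000 km² land area (geographic equity).
Regions are classed urban / suburban / rural by population density with the
standard >200 and >10 persons/km² demarcation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .region_data import RegionRecord, RegionTable, ResourceKind

__all__ = [
    "SettlementCategory",
    "WHOAssessment",
    "DensityIndicator",
    "GroupSummary",
    "POPULATION_SCALE",
    "AREA_SCALE",
    "URBAN_DENSITY_THRESHOLD",
    "SUBURBAN_DENSITY_THRESHOLD",
    "WHO_MINIMUM_WORKFORCE",
    "WHO_SDG_WORKFORCE",
    "population_density",
    "classify_region",
    "classify_table",
    "density_indicator",
    "indicator_values",
    "summarize_groups",
    "who_threshold_check",
]

#: Indicator scales: resources per 10 000 persons and per 1 000 km².
POPULATION_SCALE = 10_000.0
AREA_SCALE = 1_000.0

#: Persons/km² above which a region is urban, resp. suburban.
URBAN_DENSITY_THRESHOLD = 200.0
SUBURBAN_DENSITY_THRESHOLD = 10.0

#: WHO workforce thresholds, physicians+nurses(+midwives) per 10 000 people:
#: minimum essential-coverage standard and the SDG-era universal-coverage target.
WHO_MINIMUM_WORKFORCE = 22.8
WHO_SDG_WORKFORCE = 44.5


class SettlementCategory(str, Enum):
    URBAN = "urban"
    SUBURBAN = "suburban"
    RURAL = "rural"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


class WHOAssessment(str, Enum):
    BELOW_MINIMUM = "below_minimum"
    MEETS_MINIMUM = "meets_minimum"
    MEETS_SDG = "meets_sdg"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass(frozen=True)
class DensityIndicator:
    """One region's resource density on one basis, at full precision."""

    region: str
    resource: ResourceKind
    basis: str  # "population" or "area"
    value: float

    def __post_init__(self) -> None:
        if self.basis not in ("population", "area"):
            raise ValueError(f"basis must be 'population' or 'area', got {self.basis!r}")
        if self.value < 0:
            raise ValueError("indicator value must be non-negative")


@dataclass(frozen=True)
class GroupSummary:
    """Unweighted mean densities over one settlement category's regions.

    ``means`` maps ``(resource, basis)`` to the arithmetic mean of the
    per-region full-precision indicator values — matching how grouped means
    are conventionally tabulated for province-level comparisons (not the
    pooled count/pooled denominator ratio).
    """

    category: SettlementCategory
    n_regions: int
    means: dict[tuple[ResourceKind, str], float]

    def mean(self, resource: ResourceKind, basis: str) -> float:
        return self.means[(ResourceKind(resource), basis)]


def population_density(region: RegionRecord) -> float:
    """Persons per km²."""
    return region.population / region.area_km2


def classify_region(density: float) -> SettlementCategory:
    """Settlement category from population density (persons/km²).

    Strictly greater than 200 → urban; strictly greater than 10 → suburban;
    otherwise rural.  Densities exactly at a boundary fall to the lower
    category.
    """
    if density < 0:
        raise ValueError(f"population density must be non-negative, got {density}")
    if density > URBAN_DENSITY_THRESHOLD:
        return SettlementCategory.URBAN
    if density > SUBURBAN_DENSITY_THRESHOLD:
        return SettlementCategory.SUBURBAN
    return SettlementCategory.RURAL


def classify_table(table: RegionTable) -> dict[str, SettlementCategory]:
    """Category for every region, keyed by region name."""
    return {r.name: classify_region(population_density(r)) for r in table}


def density_indicator(
    region: RegionRecord, resource: ResourceKind, basis: str
) -> DensityIndicator:
    """Resource density: count/population×10 000 or count/area×1 000."""
    resource = ResourceKind(resource)
    if basis == "population":
        value = region.count(resource) / region.population * POPULATION_SCALE
    elif basis == "area":
        value = region.count(resource) / region.area_km2 * AREA_SCALE
    else:
        raise ValueError(f"basis must be 'population' or 'area', got {basis!r}")
    return DensityIndicator(region=region.name, resource=resource, basis=basis, value=value)


def indicator_values(table: RegionTable, resource: ResourceKind, basis: str) -> np.ndarray:
    """Vector of per-region indicator values in table order, full precision."""
    resource = ResourceKind(resource)
    scale = POPULATION_SCALE if basis == "population" else AREA_SCALE
    return table.counts(resource) / table.weights(basis) * scale


def summarize_groups(table: RegionTable) -> list[GroupSummary]:
    """One :class:`GroupSummary` per settlement category present in ``table``.

    Means are unweighted arithmetic means of the per-region full-precision
    indicators, computed for every resource on both bases.  Ordered urban,
    suburban, rural (categories absent from the table are omitted).
    """
    cats = classify_table(table)
    out: list[GroupSummary] = []
    for cat in SettlementCategory:
        members = [r for r in table if cats[r.name] is cat]
        if not members:
            continue
        means: dict[tuple[ResourceKind, str], float] = {}
        for resource in ResourceKind:
            for basis in ("population", "area"):
                vals = [density_indicator(r, resource, basis).value for r in members]
                means[(resource, basis)] = float(np.mean(vals))
        out.append(GroupSummary(category=cat, n_regions=len(members), means=means))
    return out


def who_threshold_check(workforce_density: float) -> WHOAssessment:
    """Assess a physicians+nurses per-10 000 density against WHO thresholds.

    Below 22.8 → below the minimum essential-coverage standard; at least 22.8
    but below 44.5 → meets the minimum; 44.5 or more → meets the SDG-era
    universal-coverage target.  Boundaries are inclusive at the named
    threshold.
    """
    if workforce_density < 0:
        raise ValueError(f"density must be non-negative, got {workforce_density}")
    if workforce_density >= WHO_SDG_WORKFORCE:
        return WHOAssessment.MEETS_SDG
    if workforce_density >= WHO_MINIMUM_WORKFORCE:
        return WHOAssessment.MEETS_MINIMUM
    return WHOAssessment.BELOW_MINIMUM
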