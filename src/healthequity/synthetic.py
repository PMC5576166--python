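"""Synthetic region tables with controllable inequality.

Emulates the structure of a national province table: a small number of
regions, heavy-tailed population and area sizes (symmetric Dirichlet shares
of fixed national totals), and region-level resource densities drawn
log-normal.  The log-normal scale σ controls inequality directly: for
equal-weight regions the population-basis Gini has the closed form
2Φ(σ/√2) − 1, which makes the generator a calibration instrument for the
Lorenz/Gini machinery.

What it does not emulate: spatial autocorrelation, geography, or any
systematic urban pull on densities (unless :func:`generate_separated_groups`
imposes one); regions are exchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .region_data import RegionRecord, RegionTable, ResourceKind

__all__ = ["SyntheticSpec", "generate_table", "generate_separated_groups"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic national table.

    Defaults mirror the Mongolia-like study shape: 22 regions, a ~3 million
    national population and ~1.5 million km² land area split by a symmetric
    Dirichlet with concentration 0.5 (small concentration → one or two
    dominant regions), and densities log-normal around 30 resources per
    10 000 persons with moderate dispersion.

    ``population_concentration=None`` (likewise for area) means exactly
    equal shares — the regime in which the closed-form log-normal Gini
    applies without weighting noise.
    """

    n_regions: int = 22
    seed: int = 0
    total_population: int = 3_000_000
    population_concentration: float | None = 0.5
    total_area: float = 1_500_000.0
    area_concentration: float | None = 0.5
    density_median: float = 30.0  # resources per 10 000 persons (log-normal median e^mu)
    density_sigma: float = 0.4
    resources: tuple[ResourceKind, ...] = (
        ResourceKind.PHYSICIANS,
        ResourceKind.NURSES,
        ResourceKind.HOSPITAL_BEDS,
    )

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("n_regions must be at least 2")
        if self.total_population <= 0 or self.total_area <= 0:
            raise ValueError("totals must be positive")
        for c in (self.population_concentration, self.area_concentration):
            if c is not None and c <= 0:
                raise ValueError("Dirichlet concentration must be positive")
        if self.density_sigma < 0:
            raise ValueError("density_sigma must be non-negative")
        if self.density_median <= 0:
            raise ValueError("density_median must be positive")
        if not self.resources:
            raise ValueError("at least one resource kind is required")


def _shares(rng: np.random.Generator, n: int, concentration: float | None) -> np.ndarray:
    if concentration is None:
        return np.full(n, 1.0 / n)
    return rng.dirichlet(np.full(n, concentration))


def _sizes(rng: np.random.Generator, n: int, total: float, concentration: float | None) -> np.ndarray:
    """Integer region sizes ≥ 1 from rescaled Dirichlet shares."""
    sizes = np.maximum(1, np.round(_shares(rng, n, concentration) * total)).astype(int)
    return sizes


def generate_table(spec: SyntheticSpec) -> RegionTable:
    """One reproducible synthetic region table.

    Populations and areas are rescaled Dirichlet shares of the national
    totals (rounded, minimum 1); for every requested resource each region
    draws an independent log-normal density (per 10 000 persons) and gets
    ``round(density × population / 10 000)`` units.  Identical spec and seed
    give identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    pops = _sizes(rng, spec.n_regions, spec.total_population, spec.population_concentration)
    areas = _sizes(rng, spec.n_regions, spec.total_area, spec.area_concentration)
    mu = np.log(spec.density_median)
    counts: dict[ResourceKind, np.ndarray] = {}
    for kind in spec.resources:
        dens = np.exp(rng.normal(mu, spec.density_sigma, size=spec.n_regions))
        counts[kind] = np.round(dens * pops / 10_000.0).astype(int)
    zeros = np.zeros(spec.n_regions, dtype=int)
    records = tuple(
        RegionRecord(
            name=f"region_{i:03d}",
            population=int(pops[i]),
            area_km2=float(areas[i]),
            physicians=int(counts.get(ResourceKind.PHYSICIANS, zeros)[i]),
            nurses=int(counts.get(ResourceKind.NURSES, zeros)[i]),
            hospital_beds=int(counts.get(ResourceKind.HOSPITAL_BEDS, zeros)[i]),
        )
        for i in range(spec.n_regions)
    )
    return RegionTable(regions=records, label=f"synthetic(seed={spec.seed})")


def generate_separated_groups(
    spec: SyntheticSpec,
    shift: float,
    n_urban: int = 3,
) -> RegionTable:
    """A table with a designated high-density-settlement subset.

    The first ``n_urban`` regions have their resource densities multiplied
    by ``shift`` and their land areas shrunk so population density exceeds
    the urban threshold; the remaining regions have areas enlarged where
    necessary so they classify rural.  Group membership therefore never
    depends on the density draws.  With ``shift=1`` the two groups share one
    density distribution — the null configuration for calibrating the
    urban/rural rank test.
    """
    if shift <= 0:
        raise ValueError("shift must be positive")
    if not (0 < n_urban < spec.n_regions):
        raise ValueError("n_urban must leave both groups non-empty")
    base = generate_table(spec)
    records = list(base.regions)
    for i, r in enumerate(records):
        if i < n_urban:
            records[i] = replace(
                r,
                # push population density above the urban cutoff (400 persons/km²)
                area_km2=max(r.population / 400.0, 1e-6),
                physicians=int(round(r.physicians * shift)),
                nurses=int(round(r.nurses * shift)),
                hospital_beds=int(round(r.hospital_beds * shift)),
            )
        else:
            # cap population density at 5/km² so the region stays rural
            records[i] = replace(r, area_km2=max(r.area_km2, r.population / 5.0))
    return RegionTable(regions=tuple(records), label=base.label + f" separated(shift={shift})")
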