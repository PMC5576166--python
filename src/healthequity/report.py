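"""End-to-end analysis report: indicators, group means, Gini block, rank
tests, supply categories, Lorenz plots, and the log-log density scatter.

Everything a study-style report needs from one region table, deterministic
for a given input and options, with every figure accompanied by a CSV of the
plotted values so results stay testable without image comparison.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless rendering; must precede pyplot import
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .cutoffs import SupplyCategory, categorize_table
from .indicators import (
    GroupSummary,
    classify_table,
    indicator_values,
    population_density,
    summarize_groups,
    who_threshold_check,
)
from .inference import UTestResult, compare_settlement_groups
from .lorenz_gini import (
    GiniResult,
    LorenzCurve,
    build_lorenz,
    gini_from_table,
)
from .region_data import RegionTable, ResourceKind, write_region_csv

__all__ = [
    "AnalysisReport",
    "run_full_analysis",
    "write_report",
    "plot_lorenz",
    "plot_density_scatter",
]

logger = logging.getLogger("healthequity")

BASES = ("population", "area")


@dataclass(frozen=True)
class AnalysisReport:
    """All computed outputs of one full analysis run."""

    indicators: pd.DataFrame  # region × (category, densities on both bases)
    group_summaries: list[GroupSummary]
    gini_results: list[GiniResult]  # 3 resources × 2 bases, trapezoid
    utest_results: list[UTestResult]  # 3 resources × 2 bases
    categories: dict[tuple[ResourceKind, str], dict[str, SupplyCategory]]
    provenance: dict

    def __post_init__(self) -> None:
        n_res = self.provenance.get("n_resources", 3)
        expect = n_res * len(BASES)
        if len(self.gini_results) != expect or len(self.utest_results) != expect:
            raise ValueError(
                f"expected {expect} Gini and U-test entries, got "
                f"{len(self.gini_results)} and {len(self.utest_results)}"
            )

    def gini(self, resource: ResourceKind, basis: str) -> GiniResult:
        for g in self.gini_results:
            if g.resource is ResourceKind(resource) and g.basis == basis:
                return g
        raise KeyError((resource, basis))

    def utest(self, resource: ResourceKind, basis: str) -> UTestResult:
        for u in self.utest_results:
            if u.resource is ResourceKind(resource) and u.basis == basis:
                return u
        raise KeyError((resource, basis))

    def gini_frame(self) -> pd.DataFrame:
        """Gini block in tabular form (coefficients rounded to 2 d.p.)."""
        rows = [
            {
                "resource": g.resource.value,
                "basis": g.basis,
                "gini": g.rounded(2),
                "gini_full": g.coefficient,
                "method": g.method,
            }
            for g in self.gini_results
        ]
        return pd.DataFrame(rows)

    def utest_frame(self) -> pd.DataFrame:
        rows = [
            {
                "resource": u.resource.value,
                "basis": u.basis,
                "U": u.U,
                "n_urban_suburban": u.n1,
                "n_rural": u.n2,
                "method": u.method,
                "p_two_sided": u.p_two_sided,
                "significance": u.significance,
            }
            for u in self.utest_results
        ]
        return pd.DataFrame(rows)


def _table_digest(table: RegionTable) -> str:
    payload = table.to_frame().to_csv(index=False).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()[:16]


def _indicator_frame(table: RegionTable) -> pd.DataFrame:
    cats = classify_table(table)
    df = pd.DataFrame({"region": table.names})
    df["settlement"] = [cats[n].value for n in table.names]
    df["population_density"] = [population_density(r) for r in table]
    for resource in ResourceKind:
        for basis, suffix in (("population", "per_10k_pop"), ("area", "per_1k_km2")):
            df[f"{resource.value}_{suffix}"] = indicator_values(table, resource, basis)
    workforce = (
        df["physicians_per_10k_pop"] + df["nurses_per_10k_pop"]
    )
    df["who_assessment"] = [who_threshold_check(v).value for v in workforce]
    return df


def run_full_analysis(
    table: RegionTable,
    k_classes: int = 4,
    utest_method: str = "asymptotic",
    continuity_correction: bool = True,
) -> AnalysisReport:
    """Run every pipeline stage on ``table`` and collect the results.

    Stages: per-region indicators and settlement classes; unweighted group
    means; six Gini coefficients (trapezoid method; the grouped formula
    agrees to within one part in the total weight); six urban+suburban vs
    rural rank tests; and four-class supply categories per resource and
    basis (skipped with a warning where fewer than ``k_classes`` distinct
    values exist).
    """

    def stage(name):
        logger.info("stage: %s", name)

    stage("indicators")
    ind = _indicator_frame(table)

    stage("group_summaries")
    groups = summarize_groups(table)

    stage("lorenz_gini")
    ginis = [
        gini_from_table(table, resource, basis)
        for resource in ResourceKind
        for basis in BASES
    ]

    stage("inference")
    utests = [
        compare_settlement_groups(
            table, resource, basis,
            method=utest_method, continuity_correction=continuity_correction,
        )
        for resource in ResourceKind
        for basis in BASES
    ]

    stage("cutoffs")
    categories: dict[tuple[ResourceKind, str], dict[str, SupplyCategory]] = {}
    for resource in ResourceKind:
        for basis in BASES:
            try:
                categories[(resource, basis)] = categorize_table(
                    table, resource, basis, k=k_classes
                )
            except ValueError as exc:
                logger.warning(
                    "cutoffs: skipping %s/%s (%s)", resource.value, basis, exc
                )

    provenance = {
        "label": table.label,
        "input_digest": _table_digest(table),
        "package_version": __version__,
        "n_regions": len(table),
        "n_resources": len(list(ResourceKind)),
        "k_classes": k_classes,
        "utest_method": utest_method,
        "continuity_correction": continuity_correction,
    }
    return AnalysisReport(
        indicators=ind,
        group_summaries=groups,
        gini_results=ginis,
        utest_results=utests,
        categories=categories,
        provenance=provenance,
    )


def plot_lorenz(
    curves: list[LorenzCurve],
    out_image: str | Path,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Plot Lorenz curves for one basis alongside the equality diagonal.

    Returns (and optionally writes) the tidy point table actually plotted.
    """
    if not curves:
        raise ValueError("at least one curve is required")
    frames = []
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="equality")
    for curve in curves:
        name = curve.resource.value if curve.resource else "resource"
        ax.plot(curve.p, curve.q, marker=".", ms=3, lw=1.2, label=name)
        frames.append(
            pd.DataFrame(
                {
                    "resource": name,
                    "basis": curve.basis,
                    "p_cumulative_weight_share": curve.p,
                    "q_cumulative_resource_share": curve.q,
                }
            )
        )
    basis = curves[0].basis
    ax.set_xlabel(f"cumulative {basis} share")
    ax.set_ylabel("cumulative resource share")
    ax.set_title(f"Lorenz curves ({basis} basis)")
    ax.legend(loc="upper left", fontsize=8)
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(out_image, dpi=150)
    plt.close(fig)
    points = pd.concat(frames, ignore_index=True)
    if out_csv is not None:
        points.to_csv(out_csv, index=False)
    return points


def plot_density_scatter(
    table: RegionTable,
    resource: ResourceKind,
    out_image: str | Path,
    out_csv: str | Path | None = None,
    k_classes: int = 4,
) -> pd.DataFrame:
    """Log-log scatter of per-10 000-population vs per-1 000-km² densities.

    Base-10 logarithmic axes; points coloured by the area-basis supply
    category.  Zero densities cannot be log-transformed and are excluded
    with a warning.  Returns the plotted values as a tidy table.
    """
    resource = ResourceKind(resource)
    pop_v = indicator_values(table, resource, "population")
    area_v = indicator_values(table, resource, "area")
    try:
        cats = categorize_table(table, resource, "area", k=k_classes)
    except ValueError:
        cats = {n: SupplyCategory.GREEN for n in table.names}
    df = pd.DataFrame(
        {
            "region": table.names,
            "per_10k_pop": pop_v,
            "per_1k_km2": area_v,
            "category": [cats[n].value for n in table.names],
        }
    )
    keep = (df["per_10k_pop"] > 0) & (df["per_1k_km2"] > 0)
    if not keep.all():
        logger.warning(
            "density scatter: excluding %d zero-density region(s) from the log plot",
            int((~keep).sum()),
        )
    plotted = df[keep]
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    for cat in SupplyCategory:
        sub = plotted[plotted["category"] == cat.value]
        if len(sub):
            ax.scatter(sub["per_10k_pop"], sub["per_1k_km2"], c=cat.value,
                       edgecolors="grey", s=30, label=cat.value)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(f"{resource.value} per 10 000 population (log10 scale)")
    ax.set_ylabel(f"{resource.value} per 1 000 km² (log10 scale)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_image, dpi=150)
    plt.close(fig)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


def write_report(report: AnalysisReport, table: RegionTable, outdir: str | Path) -> Path:
    """Write the full report directory; see README for the layout.

    Deterministic: the same table and options produce byte-identical CSVs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_region_csv(table, outdir / "input_table.csv")
    report.indicators.to_csv(outdir / "indicators.csv", index=False, float_format="%.10g")
    report.gini_frame().to_csv(outdir / "gini.csv", index=False, float_format="%.10g")
    report.utest_frame().to_csv(outdir / "utests.csv", index=False, float_format="%.10g")

    rows = []
    for g in report.group_summaries:
        row = {"category": g.category.value, "n_regions": g.n_regions}
        for (resource, basis), v in g.means.items():
            suffix = "per_10k_pop" if basis == "population" else "per_1k_km2"
            row[f"{resource.value}_{suffix}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "group_summaries.csv", index=False, float_format="%.10g")

    cat_rows = [
        {"region": region, "resource": resource.value, "basis": basis, "category": cat.value}
        for (resource, basis), mapping in sorted(
            report.categories.items(), key=lambda kv: (kv[0][0].value, kv[0][1])
        )
        for region, cat in mapping.items()
    ]
    pd.DataFrame(cat_rows).to_csv(outdir / "categories.csv", index=False)

    for basis in BASES:
        curves = [build_lorenz(table, resource, basis) for resource in ResourceKind]
        plot_lorenz(
            curves,
            outdir / f"lorenz_{basis}.png",
            outdir / f"lorenz_{basis}.csv",
        )
    for resource in ResourceKind:
        plot_density_scatter(
            table,
            resource,
            outdir / f"scatter_{resource.value}.png",
            outdir / f"scatter_{resource.value}.csv",
            k_classes=report.provenance["k_classes"],
        )

    pd.Series(report.provenance, dtype=object).to_json(outdir / "provenance.json", indent=2)
    return outdir
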