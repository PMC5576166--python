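"""Region-level data model, validation, CSV I/O, and the packaged Mongolia 2014 table.

The atomic record is one administrative region (for Mongolia: the capital or
an aimag/province) with its census population, land area, and raw counts of
three health-care resources.  Raw counts are authoritative everywhere in this
package; per-capita and per-area densities are always recomputed at full
precision, never stored.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "ResourceKind",
    "RegionRecord",
    "RegionTable",
    "SchemaError",
    "ValidationError",
    "REQUIRED_COLUMNS",
    "read_region_csv",
    "write_region_csv",
    "load_mongolia_2014",
]

REQUIRED_COLUMNS = (
    "region",
    "population",
    "area_km2",
    "physicians",
    "nurses",
    "hospital_beds",
)


class SchemaError(ValueError):
    """A CSV file does not have the required column structure."""


class ValidationError(ValueError):
    """A record or table violates a domain invariant."""


class ResourceKind(str, Enum):
    """The three health-care resources under study."""

    PHYSICIANS = "physicians"
    NURSES = "nurses"
    HOSPITAL_BEDS = "hospital_beds"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class RegionRecord:
    """One region's raw data: population, land area, and resource counts.

    Parameters
    ----------
    name : str
        Region label, unique within a table.
    population : int
        Resident persons; must be positive.
    area_km2 : float
        Land area in square kilometres; must be positive.
    physicians, nurses, hospital_beds : int
        Non-negative raw counts.
    """

    name: str
    population: int
    area_km2: float
    physicians: int
    nurses: int
    hospital_beds: int

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise ValidationError("region name must be non-empty")
        if not (self.population > 0):
            raise ValidationError(
                f"region {self.name!r}: population must be positive, got {self.population}"
            )
        if not (self.area_km2 > 0):
            raise ValidationError(
                f"region {self.name!r}: area_km2 must be positive, got {self.area_km2}"
            )
        for kind in ResourceKind:
            count = getattr(self, kind.value)
            if count < 0:
                raise ValidationError(
                    f"region {self.name!r}: {kind.value} must be non-negative, got {count}"
                )

    def count(self, resource: ResourceKind) -> int:
        """Raw count of ``resource`` in this region."""
        return getattr(self, ResourceKind(resource).value)


@dataclass(frozen=True)
class RegionTable:
    """An ordered collection of :class:`RegionRecord` with unique names.

    A table may hold a single region (it is still writable), but any
    concentration or comparison computation requires at least two regions;
    readers enforce that minimum.
    """

    regions: tuple[RegionRecord, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        if len(self.regions) == 0:
            raise ValidationError("a RegionTable requires at least one region")
        names = [r.name for r in self.regions]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(f"duplicate region names: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[RegionRecord]:
        return iter(self.regions)

    def __getitem__(self, key: int | str) -> RegionRecord:
        if isinstance(key, str):
            for r in self.regions:
                if r.name == key:
                    return r
            raise KeyError(key)
        return self.regions[key]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def populations(self) -> np.ndarray:
        return np.array([r.population for r in self.regions], dtype=float)

    def areas(self) -> np.ndarray:
        return np.array([r.area_km2 for r in self.regions], dtype=float)

    def counts(self, resource: ResourceKind) -> np.ndarray:
        resource = ResourceKind(resource)
        return np.array([r.count(resource) for r in self.regions], dtype=float)

    def weights(self, basis: str) -> np.ndarray:
        """Per-region weights: persons for ``basis='population'``, km² for ``'area'``."""
        if basis == "population":
            return self.populations()
        if basis == "area":
            return self.areas()
        raise ValueError(f"basis must be 'population' or 'area', got {basis!r}")

    def to_frame(self) -> pd.DataFrame:
        """Raw table as a pandas DataFrame in the CSV column order."""
        return pd.DataFrame(
            {
                "region": self.names,
                "population": [r.population for r in self.regions],
                "area_km2": [r.area_km2 for r in self.regions],
                "physicians": [r.physicians for r in self.regions],
                "nurses": [r.nurses for r in self.regions],
                "hospital_beds": [r.hospital_beds for r in self.regions],
            }
        )

    def subset(self, names: Iterable[str], label: str | None = None) -> "RegionTable":
        wanted = list(names)
        return replace(
            self,
            regions=tuple(r for r in self.regions if r.name in set(wanted)),
            label=label if label is not None else self.label,
        )


def _parse_number(raw: object, *, row: int, column: str, integer: bool) -> float:
    """Strict numeric parsing: dot decimal, no thousands separators."""
    text = str(raw).strip()
    if text == "" or text.lower() == "nan":
        raise ValidationError(f"row {row}: missing value in column {column!r}")
    if "," in text or " " in text or "_" in text:
        raise ValidationError(
            f"row {row}: column {column!r} value {text!r} contains a separator; "
            "plain digits with dot decimal required"
        )
    try:
        value = float(text)
    except ValueError as exc:
        raise ValidationError(
            f"row {row}: non-numeric value {text!r} in column {column!r}"
        ) from exc
    if integer:
        if value != int(value):
            raise ValidationError(
                f"row {row}: column {column!r} must be an integer, got {text!r}"
            )
        return int(value)
    return value


def read_region_csv(path: str | Path, label: str | None = None) -> RegionTable:
    """Read a validated region table from a UTF-8, comma-separated CSV file.

    The header must contain exactly the columns ``region, population,
    area_km2, physicians, nurses, hospital_beds`` (order free, no extras
    required but extras rejected).  At least two data rows are required.

    Raises
    ------
    SchemaError
        If a required column is missing or an unknown column present.
    ValidationError
        If a value is non-numeric, a population/area non-positive, a count
        negative, a name duplicated, or fewer than two rows present.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, encoding="utf-8")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    if extra:
        raise SchemaError(f"unexpected column(s): {extra}")
    if len(df) < 2:
        raise ValidationError(
            f"at least 2 regions are required for any analysis; file has {len(df)} data row(s)"
        )
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = dict(zip(df.columns, row))
        records.append(
            RegionRecord(
                name=unicodedata.normalize("NFC", str(d["region"]).strip()),
                population=int(_parse_number(d["population"], row=i, column="population", integer=True)),
                area_km2=_parse_number(d["area_km2"], row=i, column="area_km2", integer=False),
                physicians=int(_parse_number(d["physicians"], row=i, column="physicians", integer=True)),
                nurses=int(_parse_number(d["nurses"], row=i, column="nurses", integer=True)),
                hospital_beds=int(_parse_number(d["hospital_beds"], row=i, column="hospital_beds", integer=True)),
            )
        )
    return RegionTable(regions=tuple(records), label=label if label is not None else path.stem)


def write_region_csv(table: RegionTable, path: str | Path) -> None:
    """Write ``table`` so that :func:`read_region_csv` round-trips it exactly.

    Areas that are whole numbers are written without a decimal point so that
    integer-valued fixtures stay byte-stable.
    """
    df = table.to_frame()
    df["area_km2"] = [
        str(int(a)) if float(a) == int(a) else repr(float(a)) for a in df["area_km2"]
    ]
    df.to_csv(Path(path), index=False, encoding="utf-8")


_FIXTURE_LABEL = "Mongolia 2014"


def load_mongolia_2014() -> RegionTable:
    """The packaged 22-region Mongolia 2014 table (raw counts only).

    One row for the capital (Ulaanbaatar), two suburban provinces (Orkhon,
    Darkhan-Uul) and the 19 rural provinces, with census population, land
    area in km², and raw counts of physicians, nurses and hospital beds from
    the 2014 national health indicators.  Derived densities are never stored;
    use :mod:`healthequity.indicators` to recompute them.
    """
    source = resources.files("healthequity").joinpath("data/mongolia_2014.csv")
    with resources.as_file(source) as p:
        return read_region_csv(p, label=_FIXTURE_LABEL)
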