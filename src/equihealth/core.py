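"""Domain types and indicator construction for county-level health-resource panels.

The atomic unit of analysis is a county observed in one calendar year, carrying
its permanent population, land area, and two resource stocks (medical personnel
and beds in medical institutions).  Counties belong to a prefecture (the city or
autonomous prefecture used as the parent region for agglomeration indices) and
to a province (the parent region for Gini and Theil computations), and are
labelled impoverished or non-impoverished, the grouping variable of the study
design.

Missing resource counts are an explicit state (``None``), never coded as zero:
every downstream statistic whose input set contains a missing cell is reported
as not computable rather than silently dropped or imputed.
"""

from __future__ import annotations

from collections.abc import Callable, Iterable, Sequence
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

__all__ = [
    "Basis",
    "CountyYearRecord",
    "GroupAggregate",
    "MissingDataError",
    "Panel",
    "PanelValidationError",
    "PovertyStatus",
    "ResourceKind",
    "density_per_1000",
    "group_aggregate",
    "validate_panel",
]

SHARE_TOL = 1e-12  # closure tolerance for partition shares

CSV_COLUMNS = [
    "county_id",
    "province",
    "prefecture",
    "year",
    "poverty_status",
    "population",
    "area_km2",
    "personnel",
    "beds",
]


class ResourceKind(str, Enum):
    """Which health-resource stock an analysis refers to."""

    PERSONNEL = "personnel"
    BEDS = "beds"


class Basis(str, Enum):
    """Denominator for equality measures: demographic or geographic."""

    POPULATION = "population"
    AREA = "area"


class PovertyStatus(str, Enum):
    IMPOVERISHED = "impoverished"
    NON_IMPOVERISHED = "non_impoverished"


class PanelValidationError(ValueError):
    """A record collection violates the panel contract."""


class MissingDataError(ValueError):
    """A statistic was requested over inputs containing missing cells.

    Carries the offending (county_id, year, resource) triples so that report
    tables can state *why* a cell is not computable.
    """

    def __init__(self, message: str, cells: Sequence[tuple] = ()):  # noqa: D107
        super().__init__(message)
        self.cells = list(cells)


@dataclass(frozen=True, slots=True)
class CountyYearRecord:
    """One county observed in one year.

    Parameters
    ----------
    county_id
        Opaque identifier, stable across years.
    province, prefecture
        Administrative parents; the prefecture is the "upper and larger
        region" relative to which agglomeration degrees are defined.
    year
        Calendar year of the observation.
    poverty_status
        National poverty-county designation (fixed over the study window).
    population
        Permanent population at year end, persons (>= 0).
    area_km2
        Land area in km² (> 0; assumed constant but stored per record).
    personnel, beds
        Resource counts; ``None`` marks a missing yearbook cell.  Fractional
        values are permitted (all formulas are ratio-based).
    """

    county_id: str
    province: str
    prefecture: str
    year: int
    poverty_status: PovertyStatus
    population: float
    area_km2: float
    personnel: float | None = None
    beds: float | None = None

    def __post_init__(self) -> None:
        if self.area_km2 <= 0:
            raise PanelValidationError(
                f"county {self.county_id!r} year {self.year}: "
                f"area must be strictly positive, got {self.area_km2}"
            )
        if self.population < 0:
            raise PanelValidationError(
                f"county {self.county_id!r} year {self.year}: "
                f"population must be non-negative, got {self.population}"
            )
        for kind in ResourceKind:
            value = getattr(self, kind.value)
            if value is not None and value < 0:
                raise PanelValidationError(
                    f"county {self.county_id!r} year {self.year}: "
                    f"{kind.value} must be non-negative, got {value}"
                )

    def resource(self, kind: ResourceKind) -> float | None:
        """Return the selected resource count, or ``None`` if missing."""
        return getattr(self, ResourceKind(kind).value)


@dataclass(frozen=True)
class Panel:
    """Validated collection of county-year records.

    Invariants (enforced by :func:`validate_panel`): (county_id, year) pairs
    are unique, and every county keeps the same province, prefecture and
    poverty status across years.
    """

    records: tuple[CountyYearRecord, ...]
    missing_cells: tuple[tuple[str, int, ResourceKind], ...] = field(default=())

    @property
    def provinces(self) -> tuple[str, ...]:
        return tuple(sorted({r.province for r in self.records}))

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted({r.year for r in self.records}))

    @property
    def n_missing(self) -> int:
        return len(self.missing_cells)

    def missing_summary(self) -> pd.DataFrame:
        """Missing cells aggregated to (province, year, resource) blocks."""
        by_county = {r.county_id: r.province for r in self.records}
        rows = [
            {
                "province": by_county[cid],
                "year": year,
                "resource": kind.value,
            }
            for cid, year, kind in self.missing_cells
        ]
        if not rows:
            return pd.DataFrame(columns=["province", "year", "resource", "n_missing"])
        return (
            pd.DataFrame(rows)
            .groupby(["province", "year", "resource"], as_index=False)
            .size()
            .rename(columns={"size": "n_missing"})
        )

    def subset(self, predicate: Callable[[CountyYearRecord], bool]) -> list[CountyYearRecord]:
        return [r for r in self.records if predicate(r)]

    def slice(self, province: str, year: int) -> list[CountyYearRecord]:
        """All counties of one province in one year."""
        return [r for r in self.records if r.province == province and r.year == year]

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "county_id": r.county_id,
                    "province": r.province,
                    "prefecture": r.prefecture,
                    "year": r.year,
                    "poverty_status": r.poverty_status.value,
                    "population": r.population,
                    "area_km2": r.area_km2,
                    "personnel": r.personnel,
                    "beds": r.beds,
                }
            )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Panel":
        records = []
        for row in frame.itertuples(index=False):
            records.append(
                CountyYearRecord(
                    county_id=str(row.county_id),
                    province=str(row.province),
                    prefecture=str(row.prefecture),
                    year=int(row.year),
                    poverty_status=PovertyStatus(row.poverty_status),
                    population=float(row.population),
                    area_km2=float(row.area_km2),
                    personnel=None if pd.isna(row.personnel) else float(row.personnel),
                    beds=None if pd.isna(row.beds) else float(row.beds),
                )
            )
        return validate_panel(records)

    @classmethod
    def read_csv(cls, path) -> "Panel":
        """Read a long-format UTF-8 CSV panel; empty strings are missing."""
        frame = pd.read_csv(path, dtype={"county_id": str})
        missing = [c for c in CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise PanelValidationError(f"panel CSV lacks required columns: {missing}")
        return cls.from_frame(frame)


def validate_panel(records: Iterable[CountyYearRecord]) -> Panel:
    """Validate a record collection and assemble a :class:`Panel`.

    Raises
    ------
    PanelValidationError
        On an empty collection, a duplicated (county, year) key, or a county
        whose province, prefecture or poverty status changes across years.
    """
    records = tuple(records)
    if not records:
        raise PanelValidationError("panel must contain at least one record")

    seen: dict[tuple[str, int], CountyYearRecord] = {}
    static: dict[str, tuple[str, str, PovertyStatus]] = {}
    missing: list[tuple[str, int, ResourceKind]] = []
    for r in records:
        key = (r.county_id, r.year)
        if key in seen:
            raise PanelValidationError(f"duplicate (county, year) pair: {key}")
        seen[key] = r
        attrs = (r.province, r.prefecture, r.poverty_status)
        prior = static.setdefault(r.county_id, attrs)
        if prior != attrs:
            raise PanelValidationError(
                f"county {r.county_id!r} changes static attributes across years: "
                f"{prior} vs {attrs}"
            )
        for kind in ResourceKind:
            if r.resource(kind) is None:
                missing.append((r.county_id, r.year, kind))

    return Panel(records=records, missing_cells=tuple(missing))


def density_per_1000(record: CountyYearRecord, resource: ResourceKind) -> float | None:
    """Resource count per 1000 permanent residents: ``1000 * HR_i / P_i``.

    Missing in, missing out.  A zero population makes the density undefined.
    """
    if record.population <= 0:
        raise ZeroDivisionError(
            f"county {record.county_id!r} year {record.year}: "
            "density per 1000 capita is undefined for zero population"
        )
    value = record.resource(resource)
    if value is None:
        return None
    return 1000.0 * value / record.population


@dataclass(frozen=True)
class GroupAggregate:
    """Population/resource totals of a county group within a parent partition.

    ``ratio`` is the group's resource-to-population ratio (W_A in Theil
    notation); the two shares are the group's population and resource shares
    of the parent (G_k and T_k).
    """

    group_label: str
    total_population: float
    total_resource: float
    ratio: float
    population_share_of_parent: float
    resource_share_of_parent: float


def group_aggregate(
    records: Iterable[CountyYearRecord],
    selector: Callable[[CountyYearRecord], bool],
    parent: Callable[[CountyYearRecord], bool],
    resource: ResourceKind,
    group_label: str = "",
) -> GroupAggregate:
    """Aggregate a selected county group against its parent region.

    The selector must pick a subset of the parent; every selected county must
    carry a non-missing resource count, otherwise the aggregation is refused
    with the offending counties listed (propagation, not imputation).
    """
    resource = ResourceKind(resource)
    parent_records = [r for r in records if parent(r)]
    selected = [r for r in parent_records if selector(r)]
    if not selected:
        raise MissingDataError(f"group {group_label!r}: empty selection")

    bad = [
        (r.county_id, r.year, resource)
        for r in parent_records
        if r.resource(resource) is None
    ]
    if bad:
        raise MissingDataError(
            f"group {group_label!r}: missing {resource.value} for "
            + ", ".join(f"{c}@{y}" for c, y, _ in bad),
            cells=bad,
        )

    pop = sum(r.population for r in selected)
    res = sum(r.resource(resource) for r in selected)
    parent_pop = sum(r.population for r in parent_records)
    parent_res = sum(r.resource(resource) for r in parent_records)
    if parent_pop <= 0 or parent_res <= 0:
        raise MissingDataError(
            f"group {group_label!r}: parent totals must be positive "
            f"(population {parent_pop}, {resource.value} {parent_res})"
        )
    return GroupAggregate(
        group_label=group_label,
        total_population=pop,
        total_resource=res,
        ratio=res / pop if pop > 0 else float("nan"),
        population_share_of_parent=pop / parent_pop,
        resource_share_of_parent=res / parent_res,
    )
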