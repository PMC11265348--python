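"""Health-resource and population agglomeration degrees (HRAD / PAD).

HRAD compares a county's share of its prefecture's health resources with its
share of the prefecture's land area:

    HRAD_i = (HR_i / HR_n) / (A_i / A_n) = (HR_i / A_i) / (HR_n / A_n)

i.e. the county's resource density per km² relative to the prefecture's.
HRAD > 1 means the county is relatively rich in resources by geographical
allocation; < 1 relatively short.  PAD is the same ratio for population.
The difference HRAD − PAD judges accessibility: positive means resources
exceed the local population's proportional need (surplus), zero means the
allocation meets needs, negative a deficit.  Equivalently, sign(HRAD − PAD)
equals the sign of the county-vs-prefecture per-capita density difference.

Parent (prefecture) totals are by default the sums over the panel's counties
of that prefecture; official totals may be supplied instead when the sampled
counties do not cover the prefecture.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .core import CountyYearRecord, MissingDataError, Panel, ResourceKind

__all__ = [
    "AccessVerdict",
    "AgglomerationRecord",
    "GeographyVerdict",
    "ParentTotals",
    "agglomeration_table",
    "classify",
    "hrad",
    "pad",
    "prefecture_totals",
]

DEFAULT_TOLERANCE = 1e-9  # exact equality to 1 or 0 is measure-zero


class GeographyVerdict(str, Enum):
    RICH = "rich"
    BALANCED = "balanced"
    SHORT = "short"


class AccessVerdict(str, Enum):
    SURPLUS = "surplus"
    MEETS_NEEDS = "meets_needs"
    DEFICIT = "deficit"


@dataclass(frozen=True)
class ParentTotals:
    """Prefecture-level totals (HR_n, P_n, A_n) for one year and resource."""

    prefecture: str
    year: int
    resource_total: float | None
    population_total: float
    area_total: float


def prefecture_totals(
    records: Iterable[CountyYearRecord],
    prefecture: str,
    year: int,
    resource: ResourceKind,
) -> ParentTotals:
    """Sum panel counties of a prefecture-year into parent totals.

    A missing resource in any member county makes the resource total missing
    (propagation), while population and area totals remain usable.
    """
    resource = ResourceKind(resource)
    members = [r for r in records if r.prefecture == prefecture and r.year == year]
    if not members:
        raise MissingDataError(f"no counties for prefecture {prefecture!r} in {year}")
    values = [r.resource(resource) for r in members]
    return ParentTotals(
        prefecture=prefecture,
        year=year,
        resource_total=None if any(v is None for v in values) else float(sum(values)),
        population_total=float(sum(r.population for r in members)),
        area_total=float(sum(r.area_km2 for r in members)),
    )


def hrad(
    county: CountyYearRecord,
    parent: ParentTotals,
    resource: ResourceKind,
) -> float | None:
    """Health-resource agglomeration degree (HR_i/A_i) / (HR_n/A_n).

    Returns ``None`` when the county's or prefecture's resource is missing.
    """
    resource = ResourceKind(resource)
    if county.prefecture != parent.prefecture:
        raise ValueError(
            f"county {county.county_id!r} belongs to {county.prefecture!r}, "
            f"not {parent.prefecture!r}"
        )
    value = county.resource(resource)
    if value is None or parent.resource_total is None:
        return None
    if parent.resource_total <= 0 or parent.area_total <= 0:
        raise MissingDataError(
            f"prefecture {parent.prefecture!r} {parent.year}: "
            "parent resource and area totals must be positive"
        )
    return (value / county.area_km2) / (parent.resource_total / parent.area_total)


def pad(county: CountyYearRecord, parent: ParentTotals) -> float:
    """Population agglomeration degree (P_i/A_i) / (P_n/A_n)."""
    if county.prefecture != parent.prefecture:
        raise ValueError(
            f"county {county.county_id!r} belongs to {county.prefecture!r}, "
            f"not {parent.prefecture!r}"
        )
    if parent.population_total <= 0 or parent.area_total <= 0:
        raise MissingDataError(
            f"prefecture {parent.prefecture!r} {parent.year}: "
            "parent population and area totals must be positive"
        )
    return (county.population / county.area_km2) / (
        parent.population_total / parent.area_total
    )


def classify(
    hrad_value: float,
    pad_value: float,
    tolerance: float = DEFAULT_TOLERANCE,
) -> tuple[GeographyVerdict, AccessVerdict]:
    """Categorical verdicts from HRAD (vs 1) and HRAD − PAD (vs 0).

    A small tolerance band around the exact thresholds replaces the
    measure-zero equality branches of the defining rules.
    """
    if not (np.isfinite(hrad_value) and np.isfinite(pad_value)):
        raise ValueError("verdicts require finite HRAD and PAD")
    if hrad_value > 1.0 + tolerance:
        geography = GeographyVerdict.RICH
    elif hrad_value < 1.0 - tolerance:
        geography = GeographyVerdict.SHORT
    else:
        geography = GeographyVerdict.BALANCED
    difference = hrad_value - pad_value
    if difference > tolerance:
        access = AccessVerdict.SURPLUS
    elif difference < -tolerance:
        access = AccessVerdict.DEFICIT
    else:
        access = AccessVerdict.MEETS_NEEDS
    return geography, access


@dataclass(frozen=True)
class AgglomerationRecord:
    county_id: str
    year: int
    resource: ResourceKind
    hrad: float
    pad: float
    difference: float
    geography_verdict: GeographyVerdict
    access_verdict: AccessVerdict
    parent: ParentTotals


def agglomeration_table(
    panel: Panel,
    resources: Sequence[ResourceKind] = tuple(ResourceKind),
    *,
    parent_totals: Mapping[tuple[str, int], Mapping[str, float]] | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
) -> pd.DataFrame:
    """Long-format HRAD/PAD table, one row per county-year-resource.

    ``parent_totals`` may map ``(prefecture, year)`` to official totals with
    keys ``personnel``/``beds``/``population``/``area_km2``; otherwise the
    prefecture's sampled counties are summed.  Missing resources propagate to
    a blank row with a reason.
    """
    rows = []
    for resource in resources:
        resource = ResourceKind(resource)
        cache: dict[tuple[str, int], ParentTotals] = {}
        for r in sorted(panel.records, key=lambda r: (r.province, r.prefecture, r.year, r.county_id)):
            key = (r.prefecture, r.year)
            if key not in cache:
                if parent_totals is not None and key in parent_totals:
                    official = parent_totals[key]
                    cache[key] = ParentTotals(
                        prefecture=r.prefecture,
                        year=r.year,
                        resource_total=official.get(resource.value),
                        population_total=official["population"],
                        area_total=official["area_km2"],
                    )
                else:
                    cache[key] = prefecture_totals(panel.records, r.prefecture, r.year, resource)
            parent = cache[key]
            row = {
                "province": r.province,
                "prefecture": r.prefecture,
                "county_id": r.county_id,
                "year": r.year,
                "poverty_status": r.poverty_status.value,
                "resource": resource.value,
                "hrad": np.nan,
                "pad": np.nan,
                "difference": np.nan,
                "geography_verdict": "",
                "access_verdict": "",
                "reason": "",
            }
            try:
                h = hrad(r, parent, resource)
                p = pad(r, parent)
            except MissingDataError as exc:
                row["reason"] = f"not computable: {exc}"
                rows.append(row)
                continue
            if h is None:
                row["reason"] = (
                    f"not computable: missing {resource.value} for "
                    f"{r.county_id}@{r.year} or its prefecture"
                )
                rows.append(row)
                continue
            geography, access = classify(h, p, tolerance)
            row.update(
                hrad=h,
                pad=p,
                difference=h - p,
                geography_verdict=geography.value,
                access_verdict=access.value,
            )
            rows.append(row)
    return pd.DataFrame(rows)
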