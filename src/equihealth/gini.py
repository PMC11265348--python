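"""Lorenz curves and the Gini coefficient for county resource allocation.

Counties are treated as weighted units: the weight is the denominator of the
equality measure (permanent population for demographic equality, land area for
geographic equality) and the amount is the resource stock.  Units are sorted by
density (amount per unit weight) and the Gini coefficient is one minus twice
the trapezoidal area under the weighted Lorenz curve — the standard estimator
in the health-resource equality literature, which reduces to the textbook
formula at equal weights.  No small-sample correction is applied by default.

Qualitative bands follow the conventional income-inequality cut points, with
0.4 as the warning line: < 0.2 "absolute even", [0.2, 0.3) "relatively
average", [0.3, 0.4) intermediate, [0.4, 0.5) "large gap", >= 0.5 "huge gap".
Band intervals are closed on the left so that classification is total.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .core import (
    Basis,
    CountyYearRecord,
    MissingDataError,
    Panel,
    ResourceKind,
)

__all__ = [
    "GiniBand",
    "GiniResult",
    "classify_gini",
    "gini_coefficient",
    "gini_result",
    "gini_table",
    "lorenz_points",
]


class GiniBand(str, Enum):
    ABSOLUTE_EVEN = "absolute_even"
    RELATIVELY_AVERAGE = "relatively_average"
    INTERMEDIATE = "intermediate"
    LARGE_GAP = "large_gap"
    HUGE_GAP = "huge_gap"


@dataclass(frozen=True)
class GiniResult:
    gini: float
    basis: Basis
    resource: ResourceKind
    lorenz_points: tuple[tuple[float, float], ...]
    band: GiniBand
    n_units: int


def _as_arrays(
    units: Sequence[tuple], *, weighted: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Split (weight, amount[, id]) tuples into sorted weight/amount arrays.

    Units are ordered by ascending density, ties broken by the unit id (or
    input position) so the Lorenz curve is deterministic under permutation.
    """
    if len(units) < 2:
        raise ValueError("Lorenz construction needs at least 2 units")
    weights = np.asarray([u[0] for u in units], dtype=float)
    amounts = np.asarray([u[1] for u in units], dtype=float)
    ids = [str(u[2]) if len(u) > 2 else "" for u in units]
    if np.any(weights <= 0):
        raise ValueError("all denominator weights must be strictly positive")
    if np.any(amounts < 0):
        raise ValueError("resource amounts must be non-negative")
    if amounts.sum() <= 0:
        raise ValueError("total resource must be positive (all-zero resources)")
    density = amounts / weights
    if not weighted:
        # unweighted variant: equal-weight units, resource measured as density
        weights = np.ones_like(weights)
        amounts = density.copy()
    order = sorted(range(len(units)), key=lambda i: (density[i], ids[i], i))
    return weights[order], amounts[order]


def lorenz_points(
    units: Sequence[tuple], *, weighted: bool = True
) -> tuple[tuple[float, float], ...]:
    """Weighted Lorenz curve points from (0, 0) to (1, 1).

    Each unit is ``(weight, amount)`` or ``(weight, amount, id)``; the curve
    plots the cumulative resource share against the cumulative weight share
    with units in ascending density order.
    """
    weights, amounts = _as_arrays(units, weighted=weighted)
    x = np.concatenate([[0.0], np.cumsum(weights) / weights.sum()])
    y = np.concatenate([[0.0], np.cumsum(amounts) / amounts.sum()])
    x[-1] = 1.0
    y[-1] = 1.0
    return tuple(zip(x.tolist(), y.tolist()))


def gini_coefficient(units: Sequence[tuple], *, weighted: bool = True) -> float:
    """Gini coefficient: 1 − 2 × trapezoidal area under the Lorenz curve."""
    points = lorenz_points(units, weighted=weighted)
    pts = np.asarray(points)
    area = np.trapezoid(pts[:, 1], pts[:, 0])
    g = 1.0 - 2.0 * area
    # clamp float noise at the perfectly-equal end
    return 0.0 if abs(g) < 1e-15 else float(g)


def classify_gini(gini: float) -> GiniBand:
    """Map a Gini value in [0, 1] to its qualitative band."""
    if not 0.0 <= gini <= 1.0:
        raise ValueError(f"Gini coefficient out of range [0, 1]: {gini}")
    if gini < 0.2:
        return GiniBand.ABSOLUTE_EVEN
    if gini < 0.3:
        return GiniBand.RELATIVELY_AVERAGE
    if gini < 0.4:
        return GiniBand.INTERMEDIATE
    if gini < 0.5:
        return GiniBand.LARGE_GAP
    return GiniBand.HUGE_GAP


def gini_result(
    records: Iterable[CountyYearRecord],
    resource: ResourceKind,
    basis: Basis,
    *,
    weighted: bool = True,
) -> GiniResult:
    """Gini over one group of counties (typically a province-year slice).

    Raises :class:`MissingDataError` when any county's resource is missing,
    mirroring the propagation policy of the report tables.
    """
    resource = ResourceKind(resource)
    basis = Basis(basis)
    records = list(records)
    bad = [
        (r.county_id, r.year, resource) for r in records if r.resource(resource) is None
    ]
    if bad:
        raise MissingDataError(
            f"missing {resource.value} for "
            + ", ".join(f"{c}@{y}" for c, y, _ in bad),
            cells=bad,
        )
    units = [
        (
            r.population if basis is Basis.POPULATION else r.area_km2,
            r.resource(resource),
            r.county_id,
        )
        for r in records
    ]
    g = gini_coefficient(units, weighted=weighted)
    return GiniResult(
        gini=g,
        basis=basis,
        resource=resource,
        lorenz_points=lorenz_points(units, weighted=weighted),
        band=classify_gini(g),
        n_units=len(units),
    )


def gini_table(
    panel: Panel,
    resources: Sequence[ResourceKind] = tuple(ResourceKind),
    bases: Sequence[Basis] = tuple(Basis),
    *,
    weighted: bool = True,
) -> pd.DataFrame:
    """Per-(province, year, resource, basis) Gini table with bands.

    Cells whose inputs are missing or degenerate carry a blank value and a
    reason string instead of aborting the table.
    """
    rows = []
    for province in panel.provinces:
        for year in panel.years:
            records = panel.slice(province, year)
            if not records:
                continue
            for resource in resources:
                for basis in bases:
                    row = {
                        "province": province,
                        "year": year,
                        "resource": ResourceKind(resource).value,
                        "basis": Basis(basis).value,
                        "gini": np.nan,
                        "band": "",
                        "n_units": len(records),
                        "reason": "",
                    }
                    try:
                        res = gini_result(records, resource, basis, weighted=weighted)
                        row.update(gini=res.gini, band=res.band.value, n_units=res.n_units)
                    except (MissingDataError, ValueError) as exc:
                        row["reason"] = f"not computable: {exc}"
                    rows.append(row)
    return pd.DataFrame(rows)
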