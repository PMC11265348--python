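"""Theil-L (mean log deviation) index with within/between-group decomposition.

The Theil-L index of a set of counties weights each county by its population
share g_i and averages the log of the overall resource-to-population ratio W
over the county ratio W_i:

    I = Σ_i g_i · log(W / W_i)

Partitioned into groups (here: impoverished vs non-impoverished counties), the
index decomposes additively into a between-group term and population-share-
weighted within-group terms:

    I = I_L + Σ_k G_k · I_k,   I_L = Σ_k G_k · log(G_k / T_k)

where G_k and T_k are the group's population and resource shares of the parent
and I_k is the group's internal Theil-L.  Contribution rates are G_k·I_k / I
(within) and I_L / I (between); they sum to one whenever I is nonzero.

Natural logarithms are the default; the base only rescales all indices and
leaves contribution rates unchanged.  Counties with zero resource make the
index undefined (log of zero), so such cells are reported as not computable
rather than dropped — dropping would silently change the population shares.
"""

from __future__ import annotations

import math
from collections.abc import Callable, Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    CountyYearRecord,
    GroupAggregate,
    MissingDataError,
    Panel,
    ResourceKind,
    group_aggregate,
)

__all__ = [
    "TheilDecomposition",
    "decompose",
    "theil_between",
    "theil_tables",
    "theil_within",
]


def _log(x: np.ndarray | float, base: float | None) -> np.ndarray | float:
    return np.log(x) if base is None else np.log(x) / math.log(base)


def _check_positive(records: Sequence[CountyYearRecord], resource: ResourceKind) -> None:
    bad = []
    for r in records:
        value = r.resource(resource)
        if value is None:
            bad.append((r.county_id, r.year, "missing"))
        elif value <= 0:
            bad.append((r.county_id, r.year, "zero resource"))
        elif r.population <= 0:
            bad.append((r.county_id, r.year, "zero population"))
    if bad:
        raise MissingDataError(
            "Theil index undefined: "
            + ", ".join(f"{c}@{y} ({why})" for c, y, why in bad),
            cells=bad,
        )


def theil_within(
    records: Iterable[CountyYearRecord],
    resource: ResourceKind,
    *,
    log_base: float | None = None,
) -> float:
    """Theil-L of one county group: Σ_i g_i · log(W_group / W_i).

    g_i is the county's population share within the group and W the
    resource-to-population ratio.  A single county gives exactly zero.
    """
    resource = ResourceKind(resource)
    records = list(records)
    if not records:
        raise MissingDataError("Theil index over an empty county group")
    _check_positive(records, resource)
    pop = np.asarray([r.population for r in records], dtype=float)
    res = np.asarray([r.resource(resource) for r in records], dtype=float)
    g = pop / pop.sum()
    w_group = res.sum() / pop.sum()
    w = res / pop
    return float(np.sum(g * _log(w_group / w, log_base)))


def theil_between(
    groups: Sequence[GroupAggregate],
    *,
    log_base: float | None = None,
) -> float:
    """Between-group Theil-L: Σ_k G_k · log(G_k / T_k).

    The groups must partition their parent, so both share vectors sum to one.
    """
    if not groups:
        raise MissingDataError("between-group Theil over an empty partition")
    G = np.asarray([g.population_share_of_parent for g in groups], dtype=float)
    T = np.asarray([g.resource_share_of_parent for g in groups], dtype=float)
    for name, shares in (("population", G), ("resource", T)):
        if abs(shares.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"group {name} shares must sum to 1 (got {shares.sum():.12f}); "
                "the groups do not partition the parent"
            )
    if np.any(T <= 0):
        raise MissingDataError("between-group Theil undefined: a group has zero resource share")
    return float(np.sum(G * _log(G / T, log_base)))


@dataclass(frozen=True)
class TheilDecomposition:
    """Full within/between decomposition of one (province, year, resource) cell."""

    resource: ResourceKind
    overall: float
    within_by_group: dict[str, float]
    between: float
    group_population_shares: dict[str, float]
    group_resource_shares: dict[str, float]
    group_ratios: dict[str, float]
    contribution_within: dict[str, float | None]
    contribution_between: float | None
    county_population_shares: dict[str, dict[str, float]]
    county_ratios: dict[str, float]
    n_counties: int
    computable: bool = True
    reason: str = ""

    @classmethod
    def not_computable(cls, resource: ResourceKind, reason: str) -> "TheilDecomposition":
        return cls(
            resource=ResourceKind(resource),
            overall=float("nan"),
            within_by_group={},
            between=float("nan"),
            group_population_shares={},
            group_resource_shares={},
            group_ratios={},
            contribution_within={},
            contribution_between=None,
            county_population_shares={},
            county_ratios={},
            n_counties=0,
            computable=False,
            reason=reason,
        )


def decompose(
    records: Iterable[CountyYearRecord],
    resource: ResourceKind,
    *,
    group_key: Callable[[CountyYearRecord], str] = lambda r: r.poverty_status.value,
    log_base: float | None = None,
) -> TheilDecomposition:
    """Decompose Theil-L over a county slice into within/between-group parts.

    By default the grouping variable is poverty status, the study's design
    grouping; any record-to-label function may be supplied instead.  Missing
    or non-positive inputs yield a not-computable result with the offending
    cells in the reason string, never a partial decomposition.
    """
    resource = ResourceKind(resource)
    records = list(records)
    if not records:
        return TheilDecomposition.not_computable(resource, "empty county slice")
    try:
        _check_positive(records, resource)
    except MissingDataError as exc:
        return TheilDecomposition.not_computable(resource, str(exc))

    labels = sorted({group_key(r) for r in records})
    groups: dict[str, list[CountyYearRecord]] = {
        lbl: [r for r in records if group_key(r) == lbl] for lbl in labels
    }
    aggregates = {
        lbl: group_aggregate(
            records,
            selector=lambda r, lbl=lbl: group_key(r) == lbl,
            parent=lambda r: True,
            resource=resource,
            group_label=lbl,
        )
        for lbl in labels
    }

    within = {
        lbl: theil_within(groups[lbl], resource, log_base=log_base) for lbl in labels
    }
    between = theil_between(list(aggregates.values()), log_base=log_base)
    G = {lbl: aggregates[lbl].population_share_of_parent for lbl in labels}
    T = {lbl: aggregates[lbl].resource_share_of_parent for lbl in labels}
    overall = between + sum(G[lbl] * within[lbl] for lbl in labels)

    # contribution rates divide by the overall index: undefined when I == 0
    if overall != 0 and math.isfinite(overall):
        contrib_within: dict[str, float | None] = {
            lbl: G[lbl] * within[lbl] / overall for lbl in labels
        }
        contrib_between: float | None = between / overall
    else:
        contrib_within = {lbl: None for lbl in labels}
        contrib_between = None

    county_shares = {
        lbl: {
            r.county_id: r.population / aggregates[lbl].total_population
            for r in groups[lbl]
        }
        for lbl in labels
    }
    county_ratios = {r.county_id: r.resource(resource) / r.population for r in records}

    return TheilDecomposition(
        resource=resource,
        overall=overall,
        within_by_group=within,
        between=between,
        group_population_shares=G,
        group_resource_shares=T,
        group_ratios={lbl: aggregates[lbl].ratio for lbl in labels},
        contribution_within=contrib_within,
        contribution_between=contrib_between,
        county_population_shares=county_shares,
        county_ratios=county_ratios,
        n_counties=len(records),
    )


def theil_tables(
    panel: Panel,
    resource: ResourceKind,
    *,
    group_key: Callable[[CountyYearRecord], str] = lambda r: r.poverty_status.value,
    log_base: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Index and contribution-rate tables per (province, year) for one resource.

    Returns ``(indices, contributions)``: the first holds the overall,
    per-group within, and between indices; the second the contribution rates.
    Not-computable cells carry NaN values plus a reason.
    """
    resource = ResourceKind(resource)
    index_rows, contrib_rows = [], []
    for province in panel.provinces:
        for year in panel.years:
            records = panel.slice(province, year)
            if not records:
                continue
            dec = decompose(records, resource, group_key=group_key, log_base=log_base)
            base = {"province": province, "year": year, "resource": resource.value}
            if not dec.computable:
                index_rows.append(
                    {**base, "overall": np.nan, "between": np.nan,
                     "reason": f"not computable: {dec.reason}"}
                )
                contrib_rows.append(
                    {**base, "between": np.nan, "reason": f"not computable: {dec.reason}"}
                )
                continue
            index_rows.append(
                {
                    **base,
                    "overall": dec.overall,
                    **{f"within_{lbl}": v for lbl, v in dec.within_by_group.items()},
                    "between": dec.between,
                    "reason": "",
                }
            )
            contrib_rows.append(
                {
                    **base,
                    **{
                        f"within_{lbl}": (np.nan if v is None else v)
                        for lbl, v in dec.contribution_within.items()
                    },
                    "between": (
                        np.nan if dec.contribution_between is None else dec.contribution_between
                    ),
                    "reason": "" if dec.contribution_between is not None
                    else "contribution rates undefined: overall index is zero",
                }
            )
    return pd.DataFrame(index_rows), pd.DataFrame(contrib_rows)
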