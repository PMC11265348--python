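"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from equihealth import CountyYearRecord, PovertyStatus, validate_panel

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


def make_record(
    county_id="c1",
    province="prov_a",
    prefecture="pref_a",
    year=2015,
    poverty_status=PovertyStatus.IMPOVERISHED,
    population=100_000.0,
    area_km2=1000.0,
    personnel=500.0,
    beds=400.0,
) -> CountyYearRecord:
    return CountyYearRecord(
        county_id=county_id,
        province=province,
        prefecture=prefecture,
        year=year,
        poverty_status=poverty_status,
        population=population,
        area_km2=area_km2,
        personnel=personnel,
        beds=beds,
    )


def make_slice(populations, personnel, statuses=None, province="prov_a", year=2015):
    """Build one province-year county slice from parallel value lists."""
    n = len(populations)
    if statuses is None:
        statuses = [
            PovertyStatus.IMPOVERISHED if i < n // 2 else PovertyStatus.NON_IMPOVERISHED
            for i in range(n)
        ]
    return [
        make_record(
            county_id=f"c{i + 1:03d}",
            province=province,
            year=year,
            poverty_status=statuses[i],
            population=populations[i],
            personnel=personnel[i],
            beds=personnel[i],
        )
        for i in range(n)
    ]


def pairwise_gini(weights, amounts) -> float:
    """Weighted pairwise mean-difference Gini: Σ_ij w_i w_j |x_i − x_j| / (2 x̄).

    Independent of the Lorenz-trapezoid implementation: densities compared
    pairwise with normalised weights.
    """
    w = np.asarray(weights, dtype=float)
    x = np.asarray(amounts, dtype=float) / w
    w = w / w.sum()
    mean = float(np.sum(w * x))
    diff = np.abs(x[:, None] - x[None, :])
    return float(np.sum(w[:, None] * w[None, :] * diff) / (2.0 * mean))


def direct_mld(populations, resources) -> float:
    """One-level mean log deviation over pooled counties (natural log)."""
    pop = np.asarray(populations, dtype=float)
    res = np.asarray(resources, dtype=float)
    g = pop / pop.sum()
    w_all = res.sum() / pop.sum()
    return float(np.sum(g * np.log(w_all / (res / pop))))


@pytest.fixture
def toy_two_county_slice():
    """Two counties, equal populations, per-capita densities 1 and 3."""
    return make_slice([10_000.0, 10_000.0], [10_000.0, 30_000.0])


@pytest.fixture
def small_panel():
    """2 counties × 2 years, all fields present."""
    records = [
        make_record(county_id=c, year=y, personnel=500.0 + 10 * y0, beds=300.0)
        for c in ("c1", "c2")
        for y0, y in enumerate((2015, 2016))
    ]
    return validate_panel(records)
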