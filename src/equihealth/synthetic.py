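"""Synthetic county-panel generator with closed-form inequality truths.

The generator emulates the structure of a multi-province county survey: a few
provinces, paired groups of impoverished and non-impoverished counties of
matched size, a five-year observation window, right-skewed per-capita resource
densities with a group-level deficit in the impoverished counties, steady
annual growth, and block-missing cells for one province-year-resource (the
pattern a non-published yearbook volume leaves in real panels).

Per-1000-capita densities are lognormal.  The model is deliberately simple:
each county draws one base density per resource and follows a deterministic
multiplicative trend over years, so the cross-sectional log-scale dispersion
within a province-year equals the configured σ exactly.  Under this model the
large-n population-unweighted limits of the county-level inequality measures
have closed forms,

    Gini = 2Φ(σ/√2) − 1,        Theil-L = σ²/2,

which serve as independent truths for estimator-recovery checks.  A
multiplicative group deficit rescales every density in the group and therefore
changes between-group inequality only, never the within-group indices.
"""

from __future__ import annotations

import math
from typing import Annotated

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy.stats import norm

from .core import CountyYearRecord, Panel, PovertyStatus, ResourceKind, validate_panel

__all__ = ["ScenarioConfig", "closed_form_truth", "generate_panel"]

# county counts per poverty group per province, mirroring a 68-county,
# five-province survey layout (12+11+4+2+5 counties per group)
STUDY_LAYOUT: dict[str, int] = {
    "province_1": 12,
    "province_2": 11,
    "province_3": 4,
    "province_4": 2,
    "province_5": 5,
}


class ScenarioConfig(BaseModel):
    """Parameters of one synthetic-panel scenario.

    Densities are resources per 1000 capita.  ``density_log_mean`` is the log
    of the non-impoverished median per resource; ``poverty_deficit`` (≤ 1)
    multiplies the impoverished-group median.  ``density_log_sd`` is the
    lognormal shape σ per poverty group.  ``annual_growth`` is the per-year
    multiplicative density trend per resource.
    """

    model_config = ConfigDict(frozen=True)

    n_provinces: int = Field(default=5, ge=1)
    counties_per_group: int | dict[str, int] = Field(
        default_factory=lambda: dict(STUDY_LAYOUT)
    )
    years: tuple[int, int] = (2015, 2019)
    density_log_mean: dict[ResourceKind, float] = Field(
        default_factory=lambda: {
            ResourceKind.PERSONNEL: math.log(6.0),
            ResourceKind.BEDS: math.log(5.0),
        }
    )
    density_log_sd: dict[PovertyStatus, float] = Field(
        default_factory=lambda: {
            PovertyStatus.IMPOVERISHED: 0.35,
            PovertyStatus.NON_IMPOVERISHED: 0.45,
        }
    )
    poverty_deficit: Annotated[float, Field(gt=0.0, le=1.0)] = 0.8
    population_range: tuple[float, float] = (30_000.0, 400_000.0)
    area_range: tuple[float, float] = (500.0, 15_000.0)
    annual_growth: dict[ResourceKind, float] = Field(
        default_factory=lambda: {
            ResourceKind.PERSONNEL: 1.05,
            ResourceKind.BEDS: 1.03,
        }
    )
    counties_per_prefecture: int = Field(default=4, ge=1)
    missing_blocks: tuple[tuple[str, int, ResourceKind], ...] = (
        ("province_5", 2019, ResourceKind.PERSONNEL),
    )
    seed: int = 0

    @field_validator("density_log_sd")
    @classmethod
    def _sd_nonnegative(cls, v: dict) -> dict:
        if any(sd < 0 for sd in v.values()):
            raise ValueError("density_log_sd values must be >= 0")
        return v

    @field_validator("annual_growth")
    @classmethod
    def _growth_positive(cls, v: dict) -> dict:
        if any(g <= 0 for g in v.values()):
            raise ValueError("annual_growth values must be > 0")
        return v

    @model_validator(mode="after")
    def _ranges_ordered(self) -> "ScenarioConfig":
        for name in ("population_range", "area_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be positive and ordered, got ({lo}, {hi})")
        y0, y1 = self.years
        if y1 < y0:
            raise ValueError(f"years must be an ordered inclusive range, got ({y0}, {y1})")
        if isinstance(self.counties_per_group, int):
            if self.counties_per_group < 1:
                raise ValueError("counties_per_group must be >= 1")
        elif any(n < 1 for n in self.counties_per_group.values()):
            raise ValueError("counties_per_group entries must be >= 1")
        return self

    # ------------------------------------------------------------------ helpers

    def province_names(self) -> list[str]:
        if isinstance(self.counties_per_group, dict):
            names = sorted(self.counties_per_group)[: self.n_provinces]
            if len(names) < self.n_provinces:
                names += [
                    f"province_{i + 1}"
                    for i in range(len(names), self.n_provinces)
                ]
            return names
        return [f"province_{i + 1}" for i in range(self.n_provinces)]

    def group_size(self, province: str) -> int:
        if isinstance(self.counties_per_group, int):
            return self.counties_per_group
        return self.counties_per_group.get(province, 1)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        data = self.model_dump(mode="json")
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def generate_panel(config: ScenarioConfig, seed: int | None = None) -> Panel:
    """Draw one panel from the scenario; deterministic given the seed.

    Each county draws a static population and area (uniform), and one base
    density per resource (lognormal around the group median); yearly values
    follow the deterministic growth trend.  Counties are assigned round-robin
    to prefectures within their province; missing blocks are blanked last.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    y0, y1 = config.years
    years = range(y0, y1 + 1)
    blanks = {
        (province, year, ResourceKind(res))
        for province, year, res in config.missing_blocks
    }

    records: list[CountyYearRecord] = []
    for province in config.province_names():
        size = config.group_size(province)
        n_counties = 2 * size
        n_pref = max(1, math.ceil(n_counties / config.counties_per_prefecture))
        idx = 0
        for status in (PovertyStatus.IMPOVERISHED, PovertyStatus.NON_IMPOVERISHED):
            deficit = (
                config.poverty_deficit if status is PovertyStatus.IMPOVERISHED else 1.0
            )
            sigma = config.density_log_sd[status]
            for k in range(size):
                population = rng.uniform(*config.population_range)
                area = rng.uniform(*config.area_range)
                base = {
                    kind: deficit
                    * math.exp(config.density_log_mean[kind] + sigma * rng.standard_normal())
                    for kind in ResourceKind
                }
                prefecture = f"{province}_pref_{idx % n_pref + 1}"
                county_id = f"{province}_{status.value[:3]}_{k + 1:03d}"
                idx += 1
                for year in years:
                    counts = {}
                    for kind in ResourceKind:
                        if (province, year, kind) in blanks:
                            counts[kind.value] = None
                            continue
                        density = base[kind] * config.annual_growth[kind] ** (year - y0)
                        counts[kind.value] = density * population / 1000.0
                    records.append(
                        CountyYearRecord(
                            county_id=county_id,
                            province=province,
                            prefecture=prefecture,
                            year=year,
                            poverty_status=status,
                            population=population,
                            area_km2=area,
                            **counts,
                        )
                    )
    return validate_panel(records)


def closed_form_truth(config: ScenarioConfig) -> dict[str, dict[str, float]]:
    """Large-n unweighted Gini and Theil-L per poverty group under the model.

    For lognormal densities with shape σ the limits are Gini = 2Φ(σ/√2) − 1
    and Theil-L = σ²/2; the group median (and hence the poverty deficit and
    growth trend) does not enter either, both being scale-invariant.
    """
    out: dict[str, dict[str, float]] = {}
    for status, sigma in config.density_log_sd.items():
        out[PovertyStatus(status).value] = {
            "gini": float(2.0 * norm.cdf(sigma / math.sqrt(2.0)) - 1.0),
            "theil_l": sigma**2 / 2.0,
        }
    return out
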