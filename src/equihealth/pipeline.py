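"""Report orchestration: validate → gini → theil → agglomeration → trends.

A single invocation produces the full set of analysis tables for a panel:

* a Gini table per (province, year, resource, basis) with qualitative bands,
* Theil-L index and contribution-rate tables per resource,
* a long-format HRAD/PAD table with geography and accessibility verdicts,
* a median density-per-1000 trend table per (province, poverty group, year).

Failures are isolated per cell: a missing province-year-resource block marks
only its own rows as not computable, with a reason string, and never poisons
the other provinces' tables.  The bundle carries provenance (config echo and
an input digest) sufficient to regenerate it bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .agglomeration import DEFAULT_TOLERANCE, agglomeration_table
from .core import Basis, Panel, ResourceKind, density_per_1000
from .gini import gini_table
from .theil import theil_tables

__all__ = ["ReportBundle", "ReportConfig", "median_density_trend", "run_report"]


class ReportConfig(BaseModel):
    """Knobs of one report run (all stages share this single config)."""

    model_config = ConfigDict(frozen=True)

    resources: tuple[ResourceKind, ...] = tuple(ResourceKind)
    bases: tuple[Basis, ...] = tuple(Basis)
    log_base: float | None = Field(default=None, description="None = natural log")
    tolerance: float = DEFAULT_TOLERANCE
    weighted_gini: bool = True

    @classmethod
    def from_yaml(cls, path) -> "ReportConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


def median_density_trend(panel: Panel, resource: ResourceKind) -> pd.DataFrame:
    """Median density per 1000 capita per (province, poverty group, year).

    The median of an even-sized group is the mean of the two central values.
    Counties with a missing resource are excluded from the median and counted
    in ``n_missing``; a fully missing group is a not-computable cell.
    """
    resource = ResourceKind(resource)
    rows = []
    groups: dict[tuple[str, str, int], list] = {}
    for r in panel.records:
        groups.setdefault((r.province, r.poverty_status.value, r.year), []).append(r)
    for (province, status, year), records in sorted(groups.items()):
        densities = [density_per_1000(r, resource) for r in records]
        present = [d for d in densities if d is not None]
        n_missing = len(densities) - len(present)
        rows.append(
            {
                "province": province,
                "poverty_status": status,
                "year": year,
                "resource": resource.value,
                "median_density_per_1000": float(np.median(present)) if present else np.nan,
                "n_counties": len(records),
                "n_missing": n_missing,
                "reason": "" if present else f"not computable: all {resource.value} missing",
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ReportBundle:
    gini_table: pd.DataFrame
    theil_tables: dict[str, pd.DataFrame]
    contribution_tables: dict[str, pd.DataFrame]
    agglomeration_table: pd.DataFrame
    trend_table: pd.DataFrame
    provenance: dict

    def write(self, outdir) -> list[Path]:
        """Write the CSV set plus a run log; returns the written paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []

        def _dump(frame: pd.DataFrame, name: str) -> None:
            path = outdir / name
            frame.to_csv(path, index=False, float_format="%.10g")
            written.append(path)

        _dump(self.gini_table, "gini.csv")
        for res, frame in sorted(self.theil_tables.items()):
            _dump(frame, f"theil_{res}.csv")
        for res, frame in sorted(self.contribution_tables.items()):
            _dump(frame, f"contribution_{res}.csv")
        _dump(self.agglomeration_table, "agglomeration.csv")
        _dump(self.trend_table, "trend.csv")

        log_path = outdir / "run.log"
        log_path.write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        written.append(log_path)
        return written


def panel_digest(panel: Panel) -> str:
    """SHA-256 of the canonical CSV serialisation of a panel."""
    return hashlib.sha256(
        panel.to_frame().to_csv(index=False).encode("utf-8")
    ).hexdigest()


def run_report(panel: Panel, config: ReportConfig | None = None) -> ReportBundle:
    """Run every analysis stage over a validated panel.

    Deterministic given the inputs; per-cell failures surface as reason
    strings inside the tables rather than exceptions.
    """
    config = config or ReportConfig()
    theil = {}
    contrib = {}
    for resource in config.resources:
        indices, contributions = theil_tables(panel, resource, log_base=config.log_base)
        theil[ResourceKind(resource).value] = indices
        contrib[ResourceKind(resource).value] = contributions
    trend = pd.concat(
        [median_density_trend(panel, resource) for resource in config.resources],
        ignore_index=True,
    )
    provenance = {
        "config": json.loads(config.model_dump_json()),
        "input_digest": panel_digest(panel),
        "n_records": len(panel.records),
        "provinces": list(panel.provinces),
        "years": list(panel.years),
        "n_missing_cells": panel.n_missing,
    }
    return ReportBundle(
        gini_table=gini_table(
            panel, config.resources, config.bases, weighted=config.weighted_gini
        ),
        theil_tables=theil,
        contribution_tables=contrib,
        agglomeration_table=agglomeration_table(
            panel, config.resources, tolerance=config.tolerance
        ),
        trend_table=trend,
        provenance=provenance,
    )
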