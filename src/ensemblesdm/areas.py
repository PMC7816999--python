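"""Suitability-weighted area accounting per scenario, country and protection status.

Range size is estimated conservatively as the sum over cells of
committee average x spherical cell area: a cell where half the models
vote presence contributes half its area.  Protected fractions come from
overlaying a protected-area label raster; stability-class areas count
each classified cell with weight one (the class itself already encodes
persistence), contrasting with the suitability-weighted current range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import EnsembleSurface
from .geo import GridSpec, RasterLayer, RegionLayer, rasterize_regions
from .stability import CLASS_HIGH, CLASS_LOW, CLASS_MID, StabilitySurface

STABILITY_CLASS_NAMES = {CLASS_LOW: "low", CLASS_MID: "mid", CLASS_HIGH: "high"}


def weighted_area(
    surface: RasterLayer,
    mask: np.ndarray | None = None,
    label: int | None = None,
) -> float:
    """Sum of value x cell area (km^2) over valid (optionally labelled) cells.

    ``mask`` may be a boolean raster, or a labelled integer raster used
    together with ``label``.
    """
    vals = surface.values
    valid = surface.mask.copy()
    if mask is not None:
        mask = np.asarray(mask)
        if label is not None:
            if not np.any(mask == label):
                raise ValueError(f"label {label} absent from mask")
            valid &= mask == label
        else:
            valid &= mask.astype(bool)
    if np.nanmin(vals[surface.mask], initial=0.0) < -1e-9:
        raise ValueError("surface values must be non-negative")
    areas = surface.grid.cell_areas_km2()
    return float(np.sum(vals[valid] * areas[valid]))


def percent_change(current_area: float, future_area: float) -> float:
    """(future - current) / current x 100."""
    if current_area <= 0:
        raise ValueError("current area must be positive")
    return (future_area - current_area) / current_area * 100.0


def aggregate_protected_percent(areas, protected_percents) -> float:
    """Pooled % protected from per-region totals and per-region percentages.

    Identity: sum(area_i x pct_i) / sum(area_i); reproduces a table's
    TOTAL row from its country rows.
    """
    areas = np.asarray(areas, dtype=float)
    pct = np.asarray(protected_percents, dtype=float)
    total = areas.sum()
    if total <= 0:
        raise ValueError("total area must be positive")
    return float(np.sum(areas * pct) / total)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal rounding with ties away from zero, as printed tables use.

    Guard digits absorb binary float noise (0.9875 stored as 0.98749...9
    still rounds up to 0.988).
    """
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -decimals
    guarded = round(float(x), decimals + 8)
    return float(Decimal(repr(guarded)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class AreaReport:
    """Table-1-shaped scenario areas and Table-2-shaped stability areas."""

    scenario_table: pd.DataFrame   # rows: country x scenario
    stability_table: pd.DataFrame  # rows: country x stability class
    totals: pd.DataFrame           # per-scenario totals, % protected, % change

    def to_csv(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.scenario_table.to_csv(d / "areas_by_scenario.csv", index=False)
        self.stability_table.to_csv(d / "areas_by_stability.csv", index=False)
        self.totals.to_csv(d / "areas_totals.csv", index=False)


def _protected_mask(protected: RegionLayer | None, grid: GridSpec) -> np.ndarray:
    if protected is None or len(protected) == 0:
        return np.zeros(grid.shape, dtype=bool)
    return rasterize_regions(protected, grid) > 0


def build_area_report(
    surfaces: dict[str, EnsembleSurface],
    stability: StabilitySurface | None,
    countries: RegionLayer,
    protected: RegionLayer | None,
) -> AreaReport:
    """Weighted areas per country x scenario (+ protected %), stability-class
    areas per country, and totals with % change vs the current scenario."""
    if "current" not in surfaces:
        raise ValueError("surfaces must include the 'current' scenario")
    grid = surfaces["current"].raster.grid
    for s in surfaces.values():
        if not s.raster.grid.approx_equal(grid):
            raise ValueError("ensemble surfaces are on different grids")
    country_raster = rasterize_regions(countries, grid)
    pa_mask = _protected_mask(protected, grid)

    rows = []
    for scen, surf in surfaces.items():
        for idx, name in enumerate(countries.labels, start=1):
            in_country = country_raster == idx
            total = weighted_area(surf.raster, in_country)
            prot = weighted_area(surf.raster, in_country & pa_mask)
            rows.append(
                {
                    "scenario": scen,
                    "region": name,
                    "role": "country",
                    "weighted_area_km2": total,
                    "percent_protected": 100.0 * prot / total if total > 0 else 0.0,
                }
            )
    scenario_table = pd.DataFrame(rows)

    tot_rows = []
    current_total = None
    for scen, surf in surfaces.items():
        total = weighted_area(surf.raster)
        prot = weighted_area(surf.raster, pa_mask)
        if scen == "current":
            current_total = total
        tot_rows.append(
            {
                "scenario": scen,
                "weighted_area_km2": total,
                "percent_protected": 100.0 * prot / total if total > 0 else 0.0,
            }
        )
    totals = pd.DataFrame(tot_rows)
    if current_total and current_total > 0:
        totals["percent_change_vs_current"] = [
            0.0 if r.scenario == "current" else percent_change(current_total, r.weighted_area_km2)
            for r in totals.itertuples()
        ]

    st_rows = []
    if stability is not None:
        if not stability.grid.approx_equal(grid):
            raise ValueError("stability surface grid mismatch")
        areas = grid.cell_areas_km2()
        for cls, cls_name in STABILITY_CLASS_NAMES.items():
            # nested: a class-c cell counts for every class <= c
            cls_mask = stability.classes >= cls
            for idx, name in enumerate(countries.labels, start=1):
                m = cls_mask & (country_raster == idx)
                total = float(areas[m].sum())  # weight one per classified cell
                prot = float(areas[m & pa_mask].sum())
                st_rows.append(
                    {
                        "stability_class": cls_name,
                        "region": name,
                        "weighted_area_km2": total,
                        "percent_protected": 100.0 * prot / total if total > 0 else 0.0,
                    }
                )
    stability_table = pd.DataFrame(st_rows)
    return AreaReport(scenario_table, stability_table, totals)
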