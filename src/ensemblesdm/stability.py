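"""Climatic stability (refugia) from summed scenario ensembles.

The five normalized committee surfaces (current + four futures) are
summed per cell, giving a stability score in [0, 5].  Cells above the
90th / 95th / 99th quantile of the strictly positive scores are classed
as low / mid / high stability — climatically persistent habitat across
all time slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import EnsembleSurface
from .geo import GridSpec, RasterLayer

CLASS_NONE, CLASS_LOW, CLASS_MID, CLASS_HIGH = 0, 1, 2, 3


@dataclass
class StabilitySurface:
    grid: GridSpec
    total: RasterLayer            # sum over the 5 scenarios, in [0, 5]
    thresholds: tuple[float, float, float]  # (t90, t95, t99)
    classes: np.ndarray           # int raster in {0 none, 1 low, 2 mid, 3 high}

    def class_mask(self, cls: int) -> np.ndarray:
        return self.classes == cls


def stability_sum(surfaces: list[EnsembleSurface]) -> RasterLayer:
    """Cellwise sum of exactly five scenario surfaces; nodata where any is nodata."""
    if len(surfaces) != 5:
        raise ValueError(f"need exactly 5 scenario surfaces, got {len(surfaces)}")
    grid = surfaces[0].raster.grid
    total = np.zeros(grid.shape)
    mask = np.ones(grid.shape, dtype=bool)
    for s in surfaces:
        if not s.raster.grid.approx_equal(grid):
            raise ValueError("scenario surfaces are on different grids")
        vals = s.raster.values
        if np.nanmin(vals[s.raster.mask], initial=0.0) < -1e-9 or np.nanmax(
            vals[s.raster.mask], initial=0.0
        ) > 1.0 + 1e-9:
            raise ValueError("surface values must be in [0, 1]")
        total = total + np.where(s.raster.mask, vals, np.nan)
        mask &= s.raster.mask
    total[~mask] = np.nan
    return RasterLayer(grid, "stability_sum", total, mask)


def positive_quantiles(
    total: RasterLayer, probs: tuple[float, ...] = (0.90, 0.95, 0.99)
) -> tuple[float, ...]:
    """Quantiles of the strictly positive cells (linear interpolation)."""
    vals = total.values[total.mask]
    pos = vals[vals > 0]
    if pos.size == 0:
        raise ValueError("no strictly positive cells in the stability sum")
    return tuple(float(np.quantile(pos, p)) for p in probs)


def classify_stability(
    total: RasterLayer, thresholds: tuple[float, float, float]
) -> np.ndarray:
    """Class raster: 3 (high) if value >= t99, 2 if >= t95, 1 if >= t90, else 0."""
    t90, t95, t99 = thresholds
    if not t90 <= t95 <= t99:
        raise ValueError("thresholds must be non-decreasing")
    vals = total.values
    out = np.zeros(total.grid.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        out[(vals >= t90) & total.mask] = CLASS_LOW
        out[(vals >= t95) & total.mask] = CLASS_MID
        out[(vals >= t99) & total.mask] = CLASS_HIGH
    return out


def build_stability(
    surfaces: list[EnsembleSurface],
    probs: tuple[float, float, float] = (0.90, 0.95, 0.99),
) -> StabilitySurface:
    total = stability_sum(surfaces)
    thresholds = positive_quantiles(total, probs)
    classes = classify_stability(total, thresholds)  # type: ignore[arg-type]
    return StabilitySurface(total.grid, total, thresholds, classes)  # type: ignore[arg-type]
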