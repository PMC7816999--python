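"""Collinearity filtering of predictor layers and projection-resolution prep.

Within the calibration region, predictors are reduced to a
low-collinearity subset in two stages: first, while any layer pair has
|Pearson r| above ``r_max``, the member of the worst pair with the
larger variance inflation factor (VIF) is dropped; then, while any VIF
exceeds ``vif_max``, the layer with the largest VIF is dropped.  A
config-driven exclusion list handles layers removed a priori (e.g.
quarter-based precipitation summaries with known spatial artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import GridSpec, RasterLayer, RasterStack
from .occurrences import CalibrationRegion

_SINGULAR_TOL = 1e-12


@dataclass
class SelectionStep:
    dropped: str
    criterion: str  # "pairwise_r" or "vif"
    value: float
    partner: str | None = None  # the other member of the offending pair


@dataclass
class SelectionReport:
    input_layers: list[str]
    config_excluded: list[str]
    steps: list[SelectionStep] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    r_max: float = 0.7
    vif_max: float = 3.0

    @property
    def dropped(self) -> list[str]:
        return [s.dropped for s in self.steps]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "step": i + 1,
                "dropped": s.dropped,
                "criterion": s.criterion,
                "value": s.value,
                "partner": s.partner or "",
            }
            for i, s in enumerate(self.steps)
        ]
        return pd.DataFrame(rows, columns=["step", "dropped", "criterion", "value", "partner"])


def vif(values: np.ndarray, target: int) -> float:
    """Variance inflation factor of column ``target`` given the others.

    VIF_j = 1 / (1 - R2_j) from an OLS regression (with intercept) of
    layer j on the remaining layers.  Perfect collinearity returns +inf.
    """
    X = np.asarray(values, dtype=float)
    n, p = X.shape
    if n < 3 or n <= p:
        raise ValueError("need more observations than layers (and at least 3)")
    y = X[:, target]
    others = np.delete(X, target, axis=1)
    A = np.column_stack([np.ones(n), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot <= 0:
        return float("inf")  # constant layer: undefined, flag as unusable
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    if 1.0 - r2 < _SINGULAR_TOL:
        return float("inf")
    return float(1.0 / (1.0 - r2))


def _all_vifs(X: np.ndarray) -> np.ndarray:
    return np.array([vif(X, j) for j in range(X.shape[1])])


def select_predictors(
    stack: RasterStack,
    region: CalibrationRegion | None = None,
    config_excluded: list[str] | None = None,
    r_max: float = 0.7,
    vif_max: float = 3.0,
) -> tuple[RasterStack, SelectionReport]:
    """Greedy two-stage collinearity filter; see module docstring.

    Tie-break: when two candidates have equal VIF, the layer later in
    input order is dropped.  Statistics use valid cells inside the
    calibration region only.
    """
    config_excluded = [n for n in (config_excluded or []) if n in stack.names]
    names = [n for n in stack.names if n not in config_excluded]
    report = SelectionReport(
        input_layers=list(stack.names),
        config_excluded=config_excluded,
        r_max=r_max,
        vif_max=vif_max,
    )
    mask = region.mask if region is not None else None
    work = stack.subset(names)
    X = work.table(mask)
    if X.shape[0] <= len(names):
        raise ValueError("not enough valid cells in the calibration region")

    def corr(Xc: np.ndarray) -> np.ndarray:
        return np.corrcoef(Xc, rowvar=False)

    # stage 1: pairwise correlation
    while len(names) >= 2:
        R = np.abs(corr(X))
        np.fill_diagonal(R, 0.0)
        worst = np.unravel_index(np.argmax(R), R.shape)
        if R[worst] <= r_max:
            break
        i, j = worst
        vifs = _all_vifs(X)
        # later-in-order member loses on VIF ties (j > i by construction of argmax? not guaranteed)
        a, b = (i, j) if i < j else (j, i)
        drop = b if vifs[b] >= vifs[a] else a
        keep_partner = a if drop == b else b
        report.steps.append(
            SelectionStep(names[drop], "pairwise_r", float(R[worst]), names[keep_partner])
        )
        X = np.delete(X, drop, axis=1)
        names.pop(drop)

    # stage 2: VIF loop
    while len(names) >= 2:
        vifs = _all_vifs(X)
        worst = int(np.max(np.arange(len(names))[vifs == vifs.max()]))
        if vifs[worst] <= vif_max:
            break
        report.steps.append(SelectionStep(names[worst], "vif", float(vifs[worst])))
        X = np.delete(X, worst, axis=1)
        names.pop(worst)

    if len(names) < 2:
        raise ValueError("fewer than 2 predictors survived the collinearity filter")
    report.retained = list(names)
    return stack.subset(names), report


def upscale_stack(stack: RasterStack, factor: int = 10) -> RasterStack:
    """Block-mean aggregation by ``factor``; output cell valid iff >= 50%
    of its block is valid.  Grids not divisible by the factor are padded
    with nodata on the south/east edges."""
    if factor < 1:
        raise ValueError("factor must be at least 1")
    if factor == 1:
        return stack
    g = stack.grid
    rows = -(-g.n_rows // factor)
    cols = -(-g.n_cols // factor)
    new_grid = GridSpec(g.origin_lon, g.origin_lat, g.cell_size * factor, rows, cols)
    out_layers = []
    for lyr in stack.layers:
        vals = np.full((rows * factor, cols * factor), np.nan)
        vals[: g.n_rows, : g.n_cols] = lyr.masked()
        blocks = vals.reshape(rows, factor, cols, factor).swapaxes(1, 2)
        flat = blocks.reshape(rows, cols, factor * factor)
        finite = np.isfinite(flat)
        n_valid = finite.sum(axis=2)
        total = np.where(finite, flat, 0.0).sum(axis=2)
        ok = n_valid * 2 >= factor * factor
        mean = np.full((rows, cols), np.nan)
        np.divide(total, n_valid, out=mean, where=ok & (n_valid > 0))
        out_layers.append(RasterLayer(new_grid, lyr.name, mean, ok))
    return RasterStack(out_layers)
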