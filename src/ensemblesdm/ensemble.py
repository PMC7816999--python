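"""Cross-validation, AUC/TSS scoring, model filtering and committee averaging.

Each algorithm is evaluated by repeated stratified k-fold
cross-validation (by default ten runs of four folds: 75% training, 25%
test).  Per fold the AUC (Mann-Whitney rank form) and maximum TSS
(sensitivity + specificity - 1 over score thresholds) are recorded.
Models whose AUC *and* TSS strictly exceed the pooled mean + SD/2 are
kept; their projections are binarized at the per-model ROC-optimal
threshold and combined as a committee average (the fraction of selected
models voting presence per cell), then min-max normalized.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .geo import GridSpec, RasterLayer

logger = logging.getLogger(__name__)


@dataclass
class FitRecord:
    """One algorithm x run x fold evaluation result."""

    algorithm: str
    run: int
    fold: int
    auc: float
    tss: float
    tss_threshold: float
    selected: bool = False
    model: object | None = None  # fitted SuitabilityModel, kept for projection

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must be in [0, 1]")
        if not -1.0 <= self.tss <= 1.0:
            raise ValueError("TSS must be in [-1, 1]")


def records_frame(records: list[FitRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "algorithm": r.algorithm,
                "run": r.run,
                "fold": r.fold,
                "auc": r.auc,
                "tss": r.tss,
                "tss_threshold": r.tss_threshold,
                "selected": r.selected,
            }
            for r in records
        ]
    )


@dataclass
class EnsembleSurface:
    """Per-scenario committee-average raster in [0, 1]."""

    scenario: str
    raster: RasterLayer
    n_members: int
    norm_min: float = 0.0
    norm_max: float = 1.0


# ---------------------------------------------------------------------------
# Cross-validation partitions
# ---------------------------------------------------------------------------


def cv_partitions(
    n: int,
    folds: int = 4,
    runs: int = 10,
    seed: int = 0,
    labels: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Per-run fold assignments (list of length ``runs`` of int arrays in [0, folds)).

    Fold sizes differ by at most one; when ``labels`` is given, each
    class (presences / pseudo-absences) is partitioned separately so
    folds are stratified.
    """
    if n < folds:
        raise ValueError(f"cannot split {n} samples into {folds} folds")
    if folds < 2:
        raise ValueError("folds must be at least 2")
    rng = np.random.default_rng(seed)
    labels = np.zeros(n, dtype=int) if labels is None else np.asarray(labels)
    out = []
    for _ in range(runs):
        assign = np.empty(n, dtype=int)
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            perm = rng.permutation(idx)
            assign[perm] = np.arange(perm.size) % folds
        out.append(assign)
    return out


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(presence score > absence score), ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def max_tss(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(threshold, TSS) maximizing sensitivity + specificity - 1.

    Candidate thresholds are midpoints of consecutive sorted unique
    scores (classification rule: score >= t is presence); the smallest
    maximizing threshold wins ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("TSS needs both classes")
    uniq = np.unique(scores)
    if uniq.size == 1:
        return float(uniq[0]), 0.0
    # midpoints plus the ROC corners (classify-all thresholds), so the
    # maximum can never drop below the chance value 0
    cand = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    best_t, best_tss = cand[0], -np.inf
    for t in cand:
        pred = scores >= t
        sens = np.sum(pred & (labels == 1)) / n_pos
        spec = np.sum(~pred & (labels == 0)) / n_neg
        tss = sens + spec - 1.0
        if tss > best_tss + 1e-12:
            best_t, best_tss = t, tss
    return float(best_t), float(best_tss)


def selection_cutoff(values) -> float:
    """Mean plus half the sample (n-1) standard deviation."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    return cutoff_from_moments(float(values.mean()), float(values.std(ddof=1)))


def cutoff_from_moments(mean: float, sd: float) -> float:
    return mean + sd / 2.0


def filter_models(records: list[FitRecord]) -> list[FitRecord]:
    """Keep records whose AUC and TSS both strictly exceed the pooled
    mean + SD/2 cutoffs; falls back to the single best-TSS record when
    nothing passes (with a warning)."""
    if len(records) < 2:
        raise ValueError("need at least 2 fit records")
    aucs = [r.auc for r in records]
    tsss = [r.tss for r in records]
    auc_cut = selection_cutoff(aucs)
    tss_cut = selection_cutoff(tsss)
    for r in records:
        r.selected = r.auc > auc_cut and r.tss > tss_cut
    selected = [r for r in records if r.selected]
    if not selected:
        best = max(records, key=lambda r: r.tss)
        best.selected = True
        warnings.warn(
            "no model exceeded both cutoffs; falling back to the single "
            f"best-TSS model ({best.algorithm} run {best.run} fold {best.fold})",
            stacklevel=2,
        )
        logger.warning("model filter empty; fallback to best TSS record")
        selected = [best]
    logger.info(
        "model filter: %d/%d selected (AUC cutoff %.4f, TSS cutoff %.4f)",
        len(selected), len(records), auc_cut, tss_cut,
    )
    return selected


# ---------------------------------------------------------------------------
# Binarization and committee averaging
# ---------------------------------------------------------------------------


def binarize_projection(surface: np.ndarray, record: FitRecord) -> np.ndarray:
    """1 where score >= the record's ROC-optimal threshold, 0 below, NaN preserved."""
    surface = np.asarray(surface, dtype=float)
    t = record.tss_threshold
    valid = np.isfinite(surface)
    if valid.any():
        lo, hi = np.nanmin(surface), np.nanmax(surface)
        if t < lo or t > hi:
            warnings.warn(
                f"threshold {t:.4f} outside observed score range [{lo:.4f}, {hi:.4f}]",
                stacklevel=2,
            )
    out = np.full(surface.shape, np.nan)
    out[valid] = (surface[valid] >= t).astype(float)
    return out


def committee_average(
    binaries: list[np.ndarray],
    grid: GridSpec,
    scenario: str = "current",
    normalize: bool = True,
) -> EnsembleSurface:
    """Cellwise mean of binary rasters, min-max normalized over valid cells.

    A constant positive surface normalizes to 1 and a constant zero to 0,
    preserving the committee semantics (1 = unanimous presence).
    """
    if not binaries:
        raise ValueError("need at least one binary raster")
    shape = binaries[0].shape
    if shape != grid.shape:
        raise ValueError("binary rasters do not match the grid")
    for b in binaries:
        if b.shape != shape:
            raise ValueError("binary rasters disagree in shape")
    stackarr = np.stack([np.asarray(b, dtype=float) for b in binaries])
    mean = stackarr.mean(axis=0)  # NaN propagates where any member is nodata
    valid = np.isfinite(mean)
    norm_min, norm_max = 0.0, 1.0
    if normalize and valid.any():
        lo = float(np.nanmin(mean))
        hi = float(np.nanmax(mean))
        norm_min, norm_max = lo, hi
        if hi > lo:
            mean = np.where(valid, (mean - lo) / (hi - lo), np.nan)
        else:  # constant surface: positive -> 1, zero -> 0
            mean = np.where(valid, 1.0 if hi > 0 else 0.0, np.nan)
    layer = RasterLayer(grid, f"committee_{scenario}", mean, valid)
    return EnsembleSurface(scenario, layer, len(binaries), norm_min, norm_max)
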