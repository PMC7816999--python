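"""Per-variable response profiles and sliding-window linear smoothing.

A response profile evaluates a fitted model along one predictor while
holding every other predictor at its observed median.  Profiles are
smoothed with a windowed local-linear scheme: an ordinary least-squares
line is fitted to each block of w = ceil(span * n) consecutive points,
sliding one point at a time, and each point's smoothed value is the
average of the predictions from every window that covers it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geo import RasterStack
from .models import SuitabilityModel


@dataclass
class ResponseCurve:
    variable: str
    x: np.ndarray
    y: dict[str, np.ndarray]       # raw responses per algorithm / model id
    smoothed: dict[str, np.ndarray]
    span: float = 0.5
    degree: int = 1


def response_profile(
    model: SuitabilityModel,
    stack: RasterStack,
    variable: str,
    n_points: int = 100,
    mask: np.ndarray | None = None,
    conditioning: str = "median",
) -> tuple[np.ndarray, np.ndarray]:
    """(x, y): model scores along ``variable`` with the other layers held
    at their observed median (or mean) over the valid region."""
    if variable not in stack:
        raise KeyError(variable)
    X = stack.table(mask)
    j = stack.names.index(variable)
    col = X[:, j]
    lo, hi = col.min(), col.max()
    if hi <= lo:
        raise ValueError(f"variable {variable!r} is constant over the region")
    x = np.linspace(lo, hi, n_points)
    center = np.median(X, axis=0) if conditioning == "median" else X.mean(axis=0)
    Xq = np.tile(center, (n_points, 1))
    Xq[:, j] = x
    return x, model.predict(Xq)


def loess_window(
    x: np.ndarray, y: np.ndarray, span: float = 0.5, degree: int = 1
) -> np.ndarray:
    """Sliding-window OLS-line smoother (see module docstring).

    Requires sorted x and at least 4 points; degree is fixed at 1
    (a straight line per window).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 points")
    if np.any(np.diff(x) < 0):
        raise ValueError("x must be sorted ascending")
    if degree != 1:
        raise ValueError("only degree-1 (linear) windows are supported")
    w = math.ceil(span * n)
    if w < 2:
        w = 2
    if n < w:
        raise ValueError("window wider than the data")
    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n)
    for k in range(n - w + 1):
        sl = slice(k, k + w)
        xs, ys = x[sl], y[sl]
        xm = xs.mean()
        den = np.sum((xs - xm) ** 2)
        if den > 0:
            slope = np.sum((xs - xm) * (ys - ys.mean())) / den
        else:  # all x equal in window: fall back to the mean
            slope = 0.0
        inter = ys.mean() - slope * xm
        pred_sum[sl] += inter + slope * xs
        pred_cnt[sl] += 1
    return pred_sum / pred_cnt


def n_windows(n: int, span: float = 0.5) -> int:
    """Number of sliding windows: n - ceil(span*n) + 1."""
    return n - math.ceil(span * n) + 1


def permutation_importance(
    model: SuitabilityModel,
    X: np.ndarray,
    n_repeats: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Mean absolute prediction change when one column is permuted.

    A simple model-agnostic importance score; larger means the variable
    matters more to the fitted response.
    """
    rng = np.random.default_rng(seed)
    base = model.predict(X)
    out = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        deltas = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            deltas.append(np.mean(np.abs(model.predict(Xp) - base)))
        out[j] = np.mean(deltas)
    return out
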