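"""The five suitability learners and their pseudo-absence schemes.

Presence-only data are complemented by pseudo-absences drawn either
uniformly at random from the calibration region or uniformly from cells
*outside* a surface-range envelope (SRE: the per-variable quantile
hyper-rectangle around presence values).  Each algorithm keeps its
conventional pairing:

=================  =====================  =========================
algorithm          pseudo-absences        family
=================  =====================  =========================
maxent_like        1000, random           L1 logistic / exponential
regression_splines 100, random            piecewise-linear basis
discriminant       100, outside-SRE       per-class Gaussian mixture
bagged_trees       n_presences, out-SRE   bootstrap-aggregated trees
bioclim_envelope   100, random (eval only) percentile envelope
=================  =====================  =========================

All learners run with fixed, recorded hyperparameters (no tuning) and
expose ``predict`` returning scores in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.mixture import GaussianMixture
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler

from .geo import RasterStack
from .occurrences import CalibrationRegion, OccurrenceSet
from .geo import point_to_cell

ALGORITHMS = (
    "bioclim_envelope",
    "maxent_like",
    "regression_splines",
    "discriminant",
    "bagged_trees",
)


@dataclass(frozen=True)
class PseudoAbsenceScheme:
    mode: str  # "random" | "random_outside_sre"
    n: int
    sre_quantile: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in {"random", "random_outside_sre"}:
            raise ValueError(f"unknown pseudo-absence mode {self.mode!r}")
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if not 0.0 <= self.sre_quantile < 0.5:
            raise ValueError("sre_quantile must be in [0, 0.5)")


@dataclass(frozen=True)
class ModelSpec:
    algorithm: str
    scheme: PseudoAbsenceScheme
    hyperparameters: tuple = ()

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


def default_model_specs(n_presences: int, seed: int = 0) -> list[ModelSpec]:
    """The conventional algorithm/pseudo-absence pairings (see module docstring)."""
    return [
        ModelSpec("maxent_like", PseudoAbsenceScheme("random", 1000, seed=seed)),
        ModelSpec("regression_splines", PseudoAbsenceScheme("random", 100, seed=seed)),
        ModelSpec("discriminant", PseudoAbsenceScheme("random_outside_sre", 100, seed=seed)),
        ModelSpec(
            "bagged_trees",
            PseudoAbsenceScheme("random_outside_sre", n_presences, seed=seed),
        ),
        ModelSpec("bioclim_envelope", PseudoAbsenceScheme("random", 100, seed=seed)),
    ]


# ---------------------------------------------------------------------------
# Surface-range envelope
# ---------------------------------------------------------------------------


@dataclass
class SreEnvelope:
    """Per-layer [q, 1-q] quantile bounds of presence values."""

    lower: np.ndarray
    upper: np.ndarray
    q: float

    def inside(self, X: np.ndarray) -> np.ndarray:
        """A point is inside iff within bounds on *every* layer."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.all((X >= self.lower) & (X <= self.upper), axis=1)


def build_sre_envelope(presence_env: np.ndarray, q: float = 0.025) -> SreEnvelope:
    X = np.asarray(presence_env, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a matrix of at least 2 presence rows")
    if not 0.0 <= q < 0.5:
        raise ValueError("q must be in [0, 0.5)")
    lower = np.quantile(X, q, axis=0)
    upper = np.quantile(X, 1.0 - q, axis=0)
    return SreEnvelope(lower, upper, q)


def sample_pseudo_absences(
    scheme: PseudoAbsenceScheme,
    region: CalibrationRegion,
    stack: RasterStack,
    presences: OccurrenceSet,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``scheme.n`` distinct non-presence cells uniformly; returns (lon, lat).

    In ``random_outside_sre`` mode, eligibility additionally requires the
    cell's environment to fail the presence-based envelope test.
    """
    grid = stack.grid
    eligible = stack.valid_mask & region.mask
    if len(presences):
        rows, cols = point_to_cell(grid, presences.lon, presences.lat)
        eligible[rows, cols] = False
    if scheme.mode == "random_outside_sre":
        pres_env = stack.extract(presences.lon, presences.lat)
        env = build_sre_envelope(pres_env, scheme.sre_quantile)
        X = np.column_stack([lyr.values.ravel() for lyr in stack.layers])
        inside = env.inside(X).reshape(grid.shape)
        eligible &= ~inside
    idx = np.flatnonzero(eligible)
    if scheme.n == 0:
        return np.array([]), np.array([])
    if idx.size < scheme.n:
        raise ValueError(
            f"only {idx.size} eligible cells for {scheme.n} pseudo-absences "
            f"(deficit {scheme.n - idx.size})"
        )
    rng = np.random.default_rng(scheme.seed if seed is None else seed)
    chosen = rng.choice(idx, size=scheme.n, replace=False)
    r, c = np.unravel_index(chosen, grid.shape)
    return grid.lon_centers[c], grid.lat_centers[r]


# ---------------------------------------------------------------------------
# BIOCLIM percentile envelope
# ---------------------------------------------------------------------------


def _percentile_rank(train: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Midpoint-rank percentile of each x among the training values.

    p = (count_less + 0.5 + 0.5 * count_equal) / n, i.e. the average rank
    a tied value would take, divided by the sample size.
    """
    train = np.sort(np.asarray(train, dtype=float))
    x = np.asarray(x, dtype=float)
    less = np.searchsorted(train, x, side="left")
    leq = np.searchsorted(train, x, side="right")
    n_eq = leq - less
    return (less + 0.5 + 0.5 * n_eq) / train.size


def bioclim_score(train_env: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Classic envelope score: per layer 1 - 2|p - 0.5| with p the
    percentile rank among presences; overall score = min over layers;
    exactly 0 strictly outside the observed presence range."""
    train_env = np.asarray(train_env, dtype=float)
    if train_env.ndim != 2 or train_env.shape[0] < 2:
        raise ValueError("envelope needs at least 2 presences")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    scores = np.ones(X.shape[0])
    for j in range(train_env.shape[1]):
        col = train_env[:, j]
        p = _percentile_rank(col, X[:, j])
        s = 1.0 - 2.0 * np.abs(p - 0.5)
        s[(X[:, j] < col.min()) | (X[:, j] > col.max())] = 0.0
        scores = np.minimum(scores, s)
    return np.clip(scores, 0.0, 1.0)


# ---------------------------------------------------------------------------
# The SuitabilityModel contract and its five implementations
# ---------------------------------------------------------------------------


class SuitabilityModel:
    """Fitted model exposing predict(X) -> scores in [0, 1]."""

    algorithm: str

    def predict(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class _EnvelopeModel(SuitabilityModel):
    algorithm = "bioclim_envelope"

    def __init__(self, train_env: np.ndarray):
        self._train = np.asarray(train_env, dtype=float)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return bioclim_score(self._train, X)


class _SklearnModel(SuitabilityModel):
    def __init__(self, algorithm: str, estimator):
        self.algorithm = algorithm
        self._est = estimator
        self._constant: float | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_SklearnModel":
        if len(np.unique(y)) < 2:
            raise ValueError("degenerate training set: single class")
        self._est.fit(X, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        proba = self._est.predict_proba(X)[:, 1]
        return np.clip(proba, 0.0, 1.0)


class _MixtureDiscriminant(SuitabilityModel):
    """Mixture discriminant analysis: a small Gaussian mixture per class,
    posterior presence probability by Bayes' rule with empirical priors."""

    algorithm = "discriminant"

    def __init__(self, n_components: int = 2, seed: int = 0):
        self.n_components = n_components
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_MixtureDiscriminant":
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("degenerate training set: single class")
        self._scaler = StandardScaler().fit(X)
        Xs = self._scaler.transform(X)
        self._mixtures = {}
        self._priors = {}
        for cls in (0, 1):
            Xc = Xs[y == cls]
            k = min(self.n_components, max(1, Xc.shape[0] // 5))
            gm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                reg_covar=1e-4,
                random_state=self.seed,
                n_init=1,
            ).fit(Xc)
            self._mixtures[cls] = gm
            self._priors[cls] = Xc.shape[0] / X.shape[0]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = self._scaler.transform(np.atleast_2d(np.asarray(X, dtype=float)))
        log_joint = {
            cls: gm.score_samples(Xs) + np.log(self._priors[cls])
            for cls, gm in self._mixtures.items()
        }
        a, b = log_joint[1], log_joint[0]
        m = np.maximum(a, b)
        p1 = np.exp(a - m) / (np.exp(a - m) + np.exp(b - m))
        return np.clip(p1, 0.0, 1.0)


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "maxent_like":
        # L1-regularised logistic on linear+quadratic features: an
        # exponential-family model in the spirit of MaxEnt
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("poly", PolynomialFeatures(degree=2, include_bias=False)),
                ("clf", LogisticRegression(
                    l1_ratio=1.0, C=1.0, solver="liblinear", random_state=seed,
                    max_iter=1000,
                )),
            ]
        )
    if algorithm == "regression_splines":
        # piecewise-linear (degree-1 spline) basis + logistic link
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("hinge", SplineTransformer(degree=1, n_knots=5, include_bias=False)),
                ("clf", LogisticRegression(C=10.0, max_iter=1000, random_state=seed)),
            ]
        )
    if algorithm == "bagged_trees":
        return RandomForestClassifier(
            n_estimators=500, random_state=seed, n_jobs=1, min_samples_leaf=1
        )
    raise ValueError(f"unknown estimator {algorithm!r}")


def fit_suitability_model(
    spec: ModelSpec,
    presence_env: np.ndarray,
    pa_env: np.ndarray,
    seed: int = 0,
) -> SuitabilityModel:
    """Fit one learner on presence (1) vs pseudo-absence (0) environments.

    The envelope model is presence-only: its pseudo-absences are used
    downstream for evaluation, never in fitting.
    """
    presence_env = np.asarray(presence_env, dtype=float)
    if presence_env.shape[0] < 2:
        raise ValueError("need at least 2 presences")
    if spec.algorithm == "bioclim_envelope":
        return _EnvelopeModel(presence_env)
    pa_env = np.asarray(pa_env, dtype=float)
    X = np.vstack([presence_env, pa_env])
    y = np.concatenate([np.ones(presence_env.shape[0]), np.zeros(pa_env.shape[0])])
    if spec.algorithm == "discriminant":
        return _MixtureDiscriminant(seed=seed).fit(X, y)
    model = _SklearnModel(spec.algorithm, _make_estimator(spec.algorithm, seed))
    return model.fit(X, y)


def predict_surface(model: SuitabilityModel, stack: RasterStack) -> np.ndarray:
    """Model scores over a stack's valid cells; NaN elsewhere."""
    mask = stack.valid_mask
    X = stack.table()
    out = np.full(stack.grid.shape, np.nan)
    out[mask] = model.predict(X)
    return out
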