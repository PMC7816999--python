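"""Virtual-species worlds with known ground truth.

Generates spatially smooth, partially collinear pseudo-climate layers,
a virtual species with Gaussian per-variable responses, presence-only
samples drawn proportionally to true suitability, and random country /
protected-area polygons — everything the downstream pipeline consumes,
with the true suitability surface retained for parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import MultiPoint, box
from shapely.ops import unary_union, voronoi_diagram

from .geo import GridSpec, RasterLayer, RasterStack, RegionLayer, grid_box
from .occurrences import OccurrenceSet

SCENARIO_LABELS = ("current", "RCP45_2050", "RCP45_2070", "RCP60_2050", "RCP60_2070")


@dataclass
class VirtualSpecies:
    """Known species-climate relationship: product of Gaussian responses."""

    optima: dict[str, float]
    widths: dict[str, float]
    informative: list[str]
    suitability: RasterLayer
    nuisance: list[str] = field(default_factory=list)


@dataclass
class ScenarioSet:
    """Current + four future scenarios; each future label has >= 1 pseudo-GCM stack."""

    stacks: dict[str, list[RasterStack]]

    def __post_init__(self) -> None:
        if set(self.stacks) != set(SCENARIO_LABELS):
            raise ValueError(f"scenario labels must be exactly {SCENARIO_LABELS}")
        if len(self.stacks["current"]) != 1:
            raise ValueError("'current' must have exactly one stack")
        grid = self.current.grid
        names = self.current.names
        for label, stacks in self.stacks.items():
            for st in stacks:
                if not st.grid.approx_equal(grid) or st.names != names:
                    raise ValueError(f"stack under {label!r} disagrees in grid/layers")

    @property
    def current(self) -> RasterStack:
        return self.stacks["current"][0]

    @property
    def labels(self) -> tuple[str, ...]:
        return SCENARIO_LABELS


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], smoothness: float) -> np.ndarray:
    """Standardised Gaussian-smoothed white noise (mean 0, sd 1)."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=smoothness, mode="reflect")
    return (f - f.mean()) / f.std()


def generate_climate_scenarios(
    grid: GridSpec,
    n_layers: int = 6,
    smoothness: float = 8.0,
    collinearity: float = 0.9,
    n_gcm: int = 2,
    shift: float | np.ndarray = 1.0,
    seed: int = 0,
    gcm_noise: float = 0.3,
    gradient_weight: float = 0.5,
) -> ScenarioSet:
    """Build a 5-scenario set of pseudo-climate stacks.

    The current stack is smoothed Gaussian noise plus a latitudinal
    gradient; layer 2 is constructed to correlate with layer 1 at about
    ``collinearity`` (so the collinearity filter has work to do).  Each
    future stack is current + per-layer mean ``shift`` + an independent
    smoothed GCM perturbation of amplitude ``gcm_noise``.
    """
    if n_layers < 2:
        raise ValueError("need at least 2 layers")
    if n_gcm < 1:
        raise ValueError("need at least 1 GCM per future scenario")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    rng = np.random.default_rng(seed)
    shape = grid.shape
    _, lat = grid.center_mesh()
    lat_grad = (lat - lat.mean()) / max(lat.std(), 1e-12)

    names = [f"BIO{i + 1}" for i in range(n_layers)]
    fields = []
    for j in range(n_layers):
        f = _smooth_field(rng, shape, smoothness)
        f = (1 - gradient_weight) * f + gradient_weight * ((-1) ** j) * lat_grad
        f = (f - f.mean()) / f.std()
        fields.append(f)
    # make layer 2 a noisy copy of layer 1 at the requested correlation
    r = float(collinearity)
    fields[1] = r * fields[0] + np.sqrt(max(1 - r**2, 0.0)) * fields[1]
    fields[1] = (fields[1] - fields[1].mean()) / fields[1].std()

    def stack_from(fields_list) -> RasterStack:
        return RasterStack(
            [RasterLayer(grid, nm, vals.copy()) for nm, vals in zip(names, fields_list)]
        )

    stacks: dict[str, list[RasterStack]] = {"current": [stack_from(fields)]}
    shift = np.broadcast_to(np.asarray(shift, dtype=float), (n_layers,))
    for k, label in enumerate(SCENARIO_LABELS[1:], start=1):
        # shifts grow with horizon/forcing so scenarios are ordered
        scale = 0.5 + 0.25 * k
        gcm_stacks = []
        for _ in range(n_gcm):
            pert = [
                fields[j] + scale * shift[j] + gcm_noise * _smooth_field(rng, shape, smoothness)
                for j in range(n_layers)
            ]
            gcm_stacks.append(stack_from(pert))
        stacks[label] = gcm_stacks
    return ScenarioSet(stacks)


def make_virtual_species(
    stack: RasterStack,
    optima: dict[str, float],
    widths: dict[str, float],
    informative: list[str] | None = None,
) -> VirtualSpecies:
    """True suitability = product of per-layer Gaussians, rescaled to [0, 1].

    Rescaling divides by the maximum over valid cells, so the modal cell
    scores 1 and zero stays zero.  Layers not listed as informative have
    no effect.
    """
    if informative is None:
        informative = sorted(optima)
    if not informative:
        raise ValueError("informative layer set must not be empty")
    missing = set(informative) - set(stack.names)
    if missing:
        raise ValueError(f"informative layers not in stack: {sorted(missing)}")
    suit = np.ones(stack.grid.shape, dtype=float)
    for name in informative:
        v = stack[name].values
        suit *= np.exp(-((v - optima[name]) ** 2) / (2 * widths[name] ** 2))
    mask = stack.valid_mask
    peak = suit[mask].max()
    if peak > 0:
        suit = suit / peak
    suit = np.clip(suit, 0.0, 1.0)
    layer = RasterLayer(stack.grid, "true_suitability", suit, mask.copy())
    nuisance = [n for n in stack.names if n not in informative]
    return VirtualSpecies(dict(optima), dict(widths), list(informative), layer, nuisance)


def sample_presences(species: VirtualSpecies, n: int, seed: int = 0) -> OccurrenceSet:
    """Presence-only sample: cells drawn w/o replacement, P proportional to suitability."""
    if n < 1:
        raise ValueError("n must be at least 1")
    layer = species.suitability
    grid = layer.grid
    valid = layer.mask & (layer.values > 0)
    idx = np.flatnonzero(valid)
    if idx.size < n:
        raise ValueError(
            f"only {idx.size} cells with positive suitability, need {n}"
        )
    w = layer.values.ravel()[idx]
    rng = np.random.default_rng(seed)
    chosen = rng.choice(idx, size=n, replace=False, p=w / w.sum())
    rows, cols = np.unravel_index(chosen, grid.shape)
    lon = grid.lon_centers[cols]
    lat = grid.lat_centers[rows]
    return OccurrenceSet(lon=lon, lat=lat, source=np.repeat("synthetic", n))


def generate_region_layers(
    grid: GridSpec,
    n_countries: int = 5,
    pa_target_fraction: float = 0.3,
    seed: int = 0,
    max_tries: int = 2000,
) -> tuple[RegionLayer, RegionLayer]:
    """Random country tessellation + protected-area rectangles.

    Countries: Voronoi cells of seeded random points, clipped to the grid
    box (an exhaustive partition).  Protected areas: random rectangles
    accumulated until their union covers the target fraction of the grid
    within +-20%.
    """
    if n_countries < 1:
        raise ValueError("need at least one country")
    if not 0.0 <= pa_target_fraction <= 1.0:
        raise ValueError("pa_target_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    min_lon, min_lat, max_lon, max_lat = grid.bounds
    bbox = grid_box(grid)

    if n_countries == 1:
        countries = RegionLayer(["country_1"], [bbox], role="country")
    else:
        pts = MultiPoint(
            [
                (
                    rng.uniform(min_lon, max_lon),
                    rng.uniform(min_lat, max_lat),
                )
                for _ in range(n_countries)
            ]
        )
        cells = voronoi_diagram(pts, envelope=bbox)
        # match each Voronoi cell back to its seed point for stable labels
        geoms: list = []
        for pt in pts.geoms:
            owner = next(g for g in cells.geoms if g.intersects(pt))
            geoms.append(owner.intersection(bbox))
        countries = RegionLayer(
            [f"country_{i + 1}" for i in range(n_countries)], geoms, role="country"
        )

    total_area = bbox.area
    target = pa_target_fraction * total_area
    rects: list = []
    if pa_target_fraction > 0:
        covered = 0.0
        span_lon = max_lon - min_lon
        span_lat = max_lat - min_lat
        for _ in range(max_tries):
            if covered >= 0.95 * target:
                break
            w = rng.uniform(0.05, 0.2) * span_lon
            h = rng.uniform(0.05, 0.2) * span_lat
            x0 = rng.uniform(min_lon, max_lon - w)
            y0 = rng.uniform(min_lat, max_lat - h)
            cand = box(x0, y0, x0 + w, y0 + h)
            new_union = unary_union(rects + [cand])
            if new_union.area <= 1.2 * target:
                rects.append(cand)
                covered = new_union.area
    protected = RegionLayer(
        [f"pa_{i + 1}" for i in range(len(rects))], rects, role="protected_area"
    )
    return countries, protected
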