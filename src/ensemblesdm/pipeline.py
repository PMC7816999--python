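"""End-to-end orchestration of the ensemble modelling pipeline.

Stages, in order: simulate (synthetic world) -> prepare (clean
occurrences, calibration buffer) -> select (collinearity filter) ->
fit (per-algorithm pseudo-absences + repeated stratified CV) ->
ensemble (mean+SD/2 filter, binarize, committee average per scenario)
-> stability (summed-scenario refugia classes) -> areas (weighted area
reports) -> curves (response profiles + windowed smoothing).

One master seed fans out to per-stage and per-(algorithm, run) seeds via
``numpy.random.SeedSequence`` spawning, so a rerun with the same config
reproduces every artifact bit for bit and stages can be re-executed
independently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import areas as areas_mod
from . import curves as curves_mod
from .config import RunConfig
from .ensemble import (
    EnsembleSurface,
    FitRecord,
    auc,
    binarize_projection,
    committee_average,
    cv_partitions,
    filter_models,
    max_tss,
    records_frame,
    selection_cutoff,
)
from .geo import GridSpec, RasterLayer, RegionLayer
from .models import (
    ModelSpec,
    default_model_specs,
    fit_suitability_model,
    predict_surface,
    sample_pseudo_absences,
)
from .occurrences import CalibrationRegion, build_calibration_mask, clean_occurrences
from .predictors import select_predictors, upscale_stack
from .stability import StabilitySurface, build_stability
from .synthetic import (
    ScenarioSet,
    VirtualSpecies,
    generate_climate_scenarios,
    generate_region_layers,
    make_virtual_species,
    sample_presences,
)

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "prepare",
    "select",
    "fit",
    "ensemble",
    "stability",
    "areas",
    "curves",
)


def derive_seeds(master: int, names: list[str]) -> dict[str, int]:
    """Deterministic named child seeds (< 2^31) from one master seed."""
    children = np.random.SeedSequence(master).spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(names, children)
    }


@dataclass
class PipelineResult:
    config: RunConfig
    scenarios: ScenarioSet | None = None
    species: VirtualSpecies | None = None
    occurrences: object = None
    region: CalibrationRegion | None = None
    countries: RegionLayer | None = None
    protected: RegionLayer | None = None
    selection_report: object = None
    predictor_stack: object = None
    records: list[FitRecord] = field(default_factory=list)
    selected: list[FitRecord] = field(default_factory=list)
    surfaces: dict[str, EnsembleSurface] = field(default_factory=dict)
    stability: StabilitySurface | None = None
    area_report: areas_mod.AreaReport | None = None
    curves: list[curves_mod.ResponseCurve] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    config: RunConfig,
    through: str = "curves",
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute the pipeline up to and including stage ``through``."""
    config.validate()
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}; expected one of {STAGES}")
    stop = STAGES.index(through)
    res = PipelineResult(config=config)
    seeds = derive_seeds(
        config.seed,
        ["climate", "species", "presences", "regions", "cv", "pa", "fit"],
    )
    manifest: dict = {"seed": config.seed, "stage_seeds": seeds, "stages": []}
    res.manifest = manifest

    # --- simulate -----------------------------------------------------
    g = config.grid
    grid = GridSpec(g.origin_lon, g.origin_lat, g.cell_size, g.n_rows, g.n_cols)
    sy = config.synthetic
    res.scenarios = generate_climate_scenarios(
        grid,
        n_layers=sy.n_layers,
        smoothness=sy.smoothness,
        collinearity=sy.collinearity,
        n_gcm=sy.n_gcm,
        shift=sy.shift,
        seed=seeds["climate"],
        gcm_noise=sy.gcm_noise,
    )
    current = res.scenarios.current
    res.species = make_virtual_species(current, sy.optima, sy.widths, sorted(sy.optima))
    raw_occ = sample_presences(res.species, sy.n_presences, seed=seeds["presences"])
    res.countries, res.protected = generate_region_layers(
        grid, sy.n_countries, sy.pa_target_fraction, seed=seeds["regions"]
    )
    manifest["stages"].append({"stage": "simulate", "n_layers": sy.n_layers,
                               "n_presences_raw": len(raw_occ)})
    if stop == 0:
        return res

    # --- prepare ------------------------------------------------------
    res.occurrences = clean_occurrences(raw_occ.to_frame())
    res.region = build_calibration_mask(res.occurrences, grid, config.buffer_deg)
    manifest["stages"].append(
        {
            "stage": "prepare",
            "n_occurrences": len(res.occurrences),
            "calibration_cells": res.region.n_cells,
        }
    )
    if stop == 1:
        return res

    # --- select -------------------------------------------------------
    res.predictor_stack, res.selection_report = select_predictors(
        current,
        res.region,
        config_excluded=config.config_excluded,
        r_max=config.r_max,
        vif_max=config.vif_max,
    )
    retained = res.selection_report.retained
    manifest["stages"].append(
        {
            "stage": "select",
            "retained": retained,
            "dropped": res.selection_report.dropped,
            "config_excluded": res.selection_report.config_excluded,
        }
    )
    if stop == 2:
        return res

    # --- fit ----------------------------------------------------------
    occ = res.occurrences
    pres_env = res.predictor_stack.extract(occ.lon, occ.lat)
    specs = default_model_specs(len(occ))
    fit_seeds = derive_seeds(seeds["fit"], [s.algorithm for s in specs])
    pa_seeds = derive_seeds(seeds["pa"], [s.algorithm for s in specs])
    cv_seeds = derive_seeds(seeds["cv"], [s.algorithm for s in specs])
    res.records = []
    for spec in specs:
        res.records.extend(
            _fit_algorithm(
                spec,
                pres_env,
                res.predictor_stack,
                res.region,
                occ,
                config,
                pa_seed=pa_seeds[spec.algorithm],
                cv_seed=cv_seeds[spec.algorithm],
                fit_seed=fit_seeds[spec.algorithm],
            )
        )
    manifest["stages"].append(
        {
            "stage": "fit",
            "n_records": len(res.records),
            "mean_auc": float(np.mean([r.auc for r in res.records])),
            "mean_tss": float(np.mean([r.tss for r in res.records])),
        }
    )
    if stop == 3:
        return res

    # --- ensemble -----------------------------------------------------
    res.selected = filter_models(res.records)
    auc_cut = selection_cutoff([r.auc for r in res.records])
    tss_cut = selection_cutoff([r.tss for r in res.records])
    proj_stacks = {
        label: [
            upscale_stack(st.subset(retained), config.upscale_factor)
            for st in res.scenarios.stacks[label]
        ]
        for label in res.scenarios.labels
    }
    proj_grid = proj_stacks["current"][0].grid
    for label, stacks in proj_stacks.items():
        binaries = [
            binarize_projection(predict_surface(rec.model, st), rec)
            for rec in res.selected
            for st in stacks
        ]
        res.surfaces[label] = committee_average(binaries, proj_grid, scenario=label)
    manifest["stages"].append(
        {
            "stage": "ensemble",
            "n_selected": len(res.selected),
            "auc_cutoff": auc_cut,
            "tss_cutoff": tss_cut,
            "members_per_scenario": {
                lab: s.n_members for lab, s in res.surfaces.items()
            },
        }
    )
    if stop == 4:
        return res

    # --- stability ----------------------------------------------------
    res.stability = build_stability(
        [res.surfaces[lab] for lab in res.scenarios.labels],
        tuple(config.stability_probs),
    )
    manifest["stages"].append(
        {"stage": "stability", "thresholds": list(res.stability.thresholds)}
    )
    if stop == 5:
        return res

    # --- areas --------------------------------------------------------
    res.area_report = areas_mod.build_area_report(
        res.surfaces, res.stability, res.countries, res.protected
    )
    manifest["stages"].append(
        {
            "stage": "areas",
            "total_current_km2": float(
                res.area_report.totals.query("scenario == 'current'")[
                    "weighted_area_km2"
                ].iloc[0]
            ),
        }
    )
    if stop == 6:
        return res

    # --- curves -------------------------------------------------------
    res.curves = _build_curves(res, config)
    manifest["stages"].append({"stage": "curves", "n_curves": len(res.curves)})

    if outdir is not None:
        write_artifacts(res, outdir)
    return res


def _fit_algorithm(
    spec: ModelSpec,
    pres_env: np.ndarray,
    stack,
    region,
    occ,
    config: RunConfig,
    pa_seed: int,
    cv_seed: int,
    fit_seed: int,
) -> list[FitRecord]:
    """Ten runs of stratified k-fold CV for one algorithm.

    Pseudo-absences are redrawn each run with a run-indexed seed; per
    fold the model is fitted on the 75% training split and scored on the
    held-out 25%.
    """
    records = []
    n_pres = pres_env.shape[0]
    scheme = spec.scheme
    run_pa_seeds = derive_seeds(pa_seed, [f"run{r}" for r in range(config.runs)])
    run_cv_seeds = derive_seeds(cv_seed, [f"run{r}" for r in range(config.runs)])
    run_fit_seeds = derive_seeds(fit_seed, [f"run{r}" for r in range(config.runs)])
    for run in range(1, config.runs + 1):
        scheme_run = ModelSpec(
            spec.algorithm,
            type(scheme)(
                scheme.mode,
                scheme.n,
                config.sre_quantile,
                run_pa_seeds[f"run{run - 1}"],
            ),
        ).scheme
        pa_lon, pa_lat = sample_pseudo_absences(scheme_run, region, stack, occ)
        pa_env = (
            stack.extract(pa_lon, pa_lat)
            if pa_lon.size
            else np.empty((0, pres_env.shape[1]))
        )
        X = np.vstack([pres_env, pa_env])
        y = np.concatenate([np.ones(n_pres), np.zeros(pa_env.shape[0])]).astype(int)
        assign = cv_partitions(
            len(y), config.folds, runs=1, seed=run_cv_seeds[f"run{run - 1}"], labels=y
        )[0]
        for fold in range(1, config.folds + 1):
            test = assign == (fold - 1)
            train = ~test
            model = fit_suitability_model(
                spec, X[train & (y == 1)], X[train & (y == 0)],
                seed=run_fit_seeds[f"run{run - 1}"],
            )
            s = model.predict(X[test])
            a = auc(s, y[test])
            t, tss = max_tss(s, y[test])
            records.append(
                FitRecord(spec.algorithm, run, fold, a, tss, t, model=model)
            )
    return records


def _build_curves(res: PipelineResult, config: RunConfig) -> list:
    """Mean response per algorithm across its selected models, then smoothed."""
    curves = []
    stack = res.predictor_stack
    by_algo: dict[str, list] = {}
    for rec in res.selected:
        by_algo.setdefault(rec.algorithm, []).append(rec.model)
    for variable in stack.names:
        x = None
        raw: dict[str, np.ndarray] = {}
        smooth: dict[str, np.ndarray] = {}
        for algo, mods in by_algo.items():
            ys = []
            for m in mods:
                x, y = curves_mod.response_profile(
                    m, stack, variable, config.curve_points, res.region.mask
                )
                ys.append(y)
            raw[algo] = np.mean(ys, axis=0)
            smooth[algo] = curves_mod.loess_window(x, raw[algo], config.loess_span)
        curves.append(
            curves_mod.ResponseCurve(variable, x, raw, smooth, config.loess_span)
        )
    return curves


# ---------------------------------------------------------------------------
# Artifact output
# ---------------------------------------------------------------------------


def write_artifacts(res: PipelineResult, outdir: str | Path) -> None:
    """Write reports (CSV), rasters (GeoTIFF), regions (GeoJSON) and manifest."""
    from .geo import write_raster, write_regions

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if res.records:
        records_frame(res.records).to_csv(out / "fit_records.csv", index=False)
    if res.selection_report is not None:
        res.selection_report.to_frame().to_csv(out / "selection_steps.csv", index=False)
    for label, surf in res.surfaces.items():
        write_raster(out / f"committee_{label}.tif", surf.raster)
    if res.stability is not None:
        write_raster(out / "stability_sum.tif", res.stability.total)
        write_raster(
            out / "stability_classes.tif",
            RasterLayer(
                res.stability.grid,
                "stability_classes",
                res.stability.classes.astype(float),
                np.ones(res.stability.grid.shape, dtype=bool),
            ),
        )
    if res.area_report is not None:
        res.area_report.to_csv(out)
    if res.countries is not None:
        write_regions(out / "countries.geojson", res.countries)
    if res.protected is not None and len(res.protected):
        write_regions(out / "protected_areas.geojson", res.protected)
    if res.curves:
        import pandas as pd

        rows = []
        for c in res.curves:
            for i, xv in enumerate(c.x):
                row = {"variable": c.variable, "x": xv}
                for algo, y in c.y.items():
                    row[f"y_{algo}"] = y[i]
                for algo, y in c.smoothed.items():
                    row[f"smoothed_{algo}"] = y[i]
                rows.append(row)
        pd.DataFrame(rows).to_csv(out / "response_curves.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(res.manifest, indent=2, sort_keys=True))
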