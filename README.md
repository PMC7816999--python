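# ensemblesdm

Ensemble species distribution modelling (SDM) for presence-only data:
committee-average ensembles across climate scenarios, climatic-stability
(refugia) classification, and suitability-weighted range-area accounting
against country and protected-area layers.

The package targets the common conservation-assessment workflow in which
a species' occurrence records (field surveys, GBIF/VertNet downloads,
geocoded literature sites) are combined with bioclimatic raster layers
(BIO1–BIO19 style) to estimate current habitat suitability, project it
under future emissions scenarios (e.g. RCP 4.5 / RCP 6.0 for 2050 and
2070 across multiple global circulation models), locate climatically
stable habitat, and ask how much of it falls inside protected areas.
Everything is exercisable end to end on synthetic virtual-species worlds
with known ground truth, so the whole chain is testable without any
external downloads.

## Method

1. **Occurrence prep** — records with missing/out-of-range coordinates
   or duplicate locations are dropped; predictors are masked to a
   1-degree buffer around the presences.
2. **Predictor selection** — within the buffer, layers are reduced to a
   low-collinearity subset: pairs with |Pearson r| > 0.7 lose the member
   with the larger variance inflation factor, then layers with
   VIF = 1/(1−R²) > 3 are dropped iteratively.
3. **Five learners**, each with its conventional pseudo-absence scheme:
   an L1-regularised exponential-family model (MaxEnt-like, 1000 random
   pseudo-absences), piecewise-linear basis regression (100 random),
   mixture discriminant analysis (100 drawn outside a surface-range
   envelope), bagged decision trees (≈500 trees, one pseudo-absence per
   presence, outside-envelope), and a BIOCLIM percentile envelope
   (presence-only; 100 random pseudo-absences for evaluation).
4. **Evaluation and filtering** — ten runs of stratified four-fold
   cross-validation (75% train / 25% test); per fold the AUC
   (Mann–Whitney rank form) and maximum TSS (sensitivity + specificity
   − 1) are recorded. Models whose AUC *and* TSS strictly exceed the
   pooled mean + SD/2 are kept.
5. **Committee average** — each selected model's projection is binarized
   at its ROC-optimal threshold; the cellwise mean of the binaries
   (across models, and across GCM variants for future scenarios) is
   min–max normalized, so 1 = unanimous presence, 0 = unanimous absence,
   0.5 = maximal disagreement.
6. **Stability / refugia** — the five normalized scenario surfaces are
   summed (range [0, 5]); cells above the 90th / 95th / 99th quantile of
   the positive values are classed low / mid / high stability.
7. **Area accounting** — range size is Σ cell (committee average ×
   spherical cell area, R = 6371 km); protected fractions and % change
   vs the current scenario are reported per country and in total.

## Worked example

Run the bundled synthetic demo (100×100 grid, 6 pseudo-climate layers
of which 2 drive the species, 150 presences, 2 pseudo-GCMs per future
scenario):

```python
import numpy as np
from ensemblesdm import RunConfig, run_pipeline

res = run_pipeline(RunConfig(seed=1), through="areas")
sel = res.selected
print(f"fit records: {len(res.records)}  selected: {len(sel)}")
print(f"mean AUC of selected models: {np.mean([r.auc for r in sel]):.3f}")
print(res.area_report.totals.round(2).to_string(index=False))
```

prints (about a minute on one CPU):

```
fit records: 200  selected: 68
mean AUC of selected models: 0.900
  scenario  weighted_area_km2  percent_protected  percent_change_vs_current
   current          602001.63              32.07                       0.00
RCP45_2050          424112.97              29.59                     -29.55
RCP45_2070          384141.72              29.49                     -36.19
RCP60_2050          324035.43              26.62                     -46.17
RCP60_2070          269758.08              26.05                     -55.19
```

200 records = 5 algorithms × 10 CV runs × 4 folds; 68 of them pass the
mean + SD/2 filter on both metrics and form the committee. The area
table reads: the current suitability-weighted range is ~602,000 km², of
which 32% falls inside the synthetic protected areas; under the
(deliberately adverse) simulated climate shifts the weighted range
contracts by 30–55%. On this world the committee surface correlates
with the true suitability at Spearman ρ ≈ 0.81.

The same pipeline is available from the shell:

```bash
ensemblesdm init-config demo.yml
ensemblesdm run-all --config demo.yml --out sdm_run
```

which writes committee rasters (`committee_*.tif`), stability classes,
Table-style CSV reports and a `manifest.json` recording every seed and
cutoff. All stage subcommands (`simulate`, `prepare`, `select-vars`,
`fit`, `ensemble`, `stability`, `areas`, `curves`) replay
deterministically from the same config.

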