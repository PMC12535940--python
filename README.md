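# retrohab

Retrospective hierarchical habitat mapping from optical satellite time
series.

Long-term monitoring of alpine protected areas faces a chicken-and-egg
problem: decades of Landsat-class imagery exist, but ground truth usually
exists for a single epoch — one good cartography made by a park authority.
`retrohab` implements a workflow that turns that single dated reference
map into *annual* training data and multi-decadal land-cover and habitat
maps:

1. **Snow-aware seasonal compositing** — scenes are terrain-corrected
   (improved cosine, `L' = L + L(⟨cos i⟩ − cos i)/⟨cos i⟩`), filtered at
   70% scene cloud cover, and fused into one growing-season and one
   senescence best-available-pixel (BAP) composite per year by a
   six-criterion weighted score (sensor, day-of-year proximity, distance
   to cloud, distance to snow, scene snow-free fraction, opacity), from
   which spectral indices (NDVI and friends) are computed.
2. **Z-statistic retrospective ground truthing** — per class `c` and
   predictor `b`, the reference epoch yields signatures (μ_cb, σ_cb); a
   pixel with predictor vector x in year T₂ gets
   `Z = sqrt(Σ_b ((x_b − μ_cb)/σ_cb)²)`, and only pixels near the centre
   of their class's Z distribution (inner half by default) are kept as
   unchanged, "pure" training samples for that year.
3. **Predictor selection** — direction-free one-vs-rest ROC AUC screening
   (keep AUC ≥ 0.75 for ≥ 1 class), a Boruta-style shadow-feature test
   (binomial test of importance-vs-best-shadow hits), and Kendall τ-b
   pruning of collinear pairs (|τ| > 0.9).
4. **Hierarchical ensemble classification** — per year, five random
   forests (100 trees, mtry 16, min node size 4, sample fraction 0.51)
   vote per pixel for land cover (rocks, snow, water, broadleaved,
   coniferous, grassland, shrubland, wetland); habitats are then
   classified *within* each vegetated land-cover class by its own
   ensemble, so a habitat label can never contradict its land cover.
5. **Temporal filtering and change detection** — three cleaning rules
   (±3-year modal gap filling, persistent-water enforcement, singleton
   removal), decadal modal aggregation, trajectory typing
   (stable / transition / mixed), class-to-class transition matrices in
   hectares and percent (cells < 1% excluded from reports), OLS
   area-change rates (ha yr⁻¹) by region and altitudinal belt, and
   starred NDVI/climate trend tests.
6. **Validation** — confusion matrices (rows predicted, columns
   reference), OA/BA/κ/weighted accuracy, per-class PA/UA/F1/TSS, patch
   metrics (8-connected), and accuracy-vs-patch-structure correlations.

A first-class synthetic module generates elevation-structured alpine
worlds — terrain, class maps, phenology, slope illumination, cloud/snow
occlusions, and a ledger of planted class transitions — so the entire
workflow is testable end-to-end without downloading anything.

## Worked example

```python
import numpy as np
from retrohab import (generate_world, plant_changes, render_scenes,
                      ReferenceMap, run_pipeline, ClassMapSeries)

world = generate_world(seed=42, shape=(96, 96), years=list(range(2005, 2013)))
plant_changes(world, [(2008, 6, 7, 2, 12)])          # grassland -> shrubland
scenes = render_scenes(world, scenes_per_season=3, noise_sd=0.01, cloud_frac=0.1)

reference = ReferenceMap(
    l1=world.dtm.like(world.true_l1[2005], nodata=0),
    reference_year=2005, legend=world.legend,
)
truth = ClassMapSeries(years=world.years, maps=world.l1_series_maps(),
                       legend=world.legend)
result = run_pipeline(scenes, world.dtm, reference, world.years,
                      master_seed=42, truth_series=truth)

print("overall accuracy:", round(result.metrics["oa"], 3),
      " kappa:", round(result.metrics["kappa"], 3))
types = np.asarray(result.trajectory_types.values)
typed = types > 0
print("stable / transition / mixed (%):",
      [round(100 * (types[typed] == k).mean(), 2) for k in (1, 2, 3)])
print("grassland rate (ha/yr):", round(result.change_rates[6], 2),
      " shrubland rate (ha/yr):", round(result.change_rates[7], 2))
print(result.transitions.report().round(2).to_string(index=False))
```

prints

```
overall accuracy: 0.999  kappa: 0.999
stable / transition / mixed (%): [99.63, 0.37, 0.0]
grassland rate (ha/yr): -0.39  shrubland rate (ha/yr): 0.39
 from  to  area_ha   pct
    3   8     0.09  2.94
    5   8     0.81 26.47
    6   7     2.16 70.59
```

Read: the cleaned annual maps agree with the synthetic truth almost
everywhere; 99.6% of pixels keep one class across both aggregation
windows; the two planted grassland→shrubland patches dominate the
transition budget (70.6% of changed area, 2.16 ha), grassland shrinks and
shrubland grows at matching rates (±0.39 ha yr⁻¹), and the residual
entries are boundary flickers around the lake's wetland fringe.

## Command line

Every stage also runs from a shell against one YAML configuration, writing
its products (GeoTIFF maps, CSV tables, JSON metrics, joblib model
archives with JSON manifests) into a run directory:

```bash
retrohab all --config run.yaml --verbose     # or stage by stage:
retrohab simulate   --config run.yaml
retrohab composite  --config run.yaml
...
retrohab trends     --config run.yaml
```

Stages are idempotent given the same inputs and seed, and a stage whose
upstream products are missing names the stage to run first. All
operational constants (cloud threshold 70%, AUC 0.75, τ 0.9, RF
hyperparameters, season windows, aggregation periods, elevation belts)
are documented configuration defaults, not hard-coded literals.

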