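# Methods

`retrohab` reconstructs multi-decadal land-cover and habitat maps of an
alpine landscape from optical satellite scene stacks and a *single* dated
reference cartography. This note documents the models and procedures the
package implements, the defaults it ships, the synthetic study it is
validated on, and the limits of what those validations show.

## Terrain correction and seasonal compositing

Every scene is corrected for topographic illumination before compositing.
The illumination angle cosine is

    cos i = cos(theta_z) cos(S) + sin(theta_z) sin(S) cos(phi - A)

with solar zenith `theta_z`, solar azimuth `phi`, slope `S` and aspect `A`
(clockwise from north). The *improved cosine* correction is additive:

    L' = L + L (⟨cos i⟩ - cos i) / ⟨cos i⟩

where `⟨cos i⟩` is the scene mean over valid, unmasked land pixels. A pixel
at mean illumination is a fixed point and a flat scene passes through
unchanged. The correction is first-order: on very steep, broken terrain a
residual remains — the classic limitation of radiometric correction in
mountain imagery, and the reason the classifier also receives
illumination-invariant normalized-difference indices (the per-pixel
illumination factor is band-independent, so it cancels exactly in a
normalized ratio).

Scenes with whole-scene cloud cover strictly above 70% are discarded.
Surviving observations compete per pixel and season under a six-criterion
weighted score (weights uniform at 1/6 by default, all configurable):

| criterion | score function | default |
| --- | --- | --- |
| sensor | lookup table, 1.0 if unlisted | all 1.0 |
| day-of-year | Gaussian around the seasonal target | growing Aug 1, senescence Oct 15, sigma 15 d |
| distance to cloud/shadow | smoothstep sigmoid, 0.5 at midpoint, 1 beyond 2x | midpoint 10 px |
| distance to snow | same form | midpoint 10 px |
| scene snow-free fraction | fraction itself | — |
| opacity | 1 - opacity, 1.0 when absent | — |

The two snow criteria adapt the scoring to alpine conditions: they favour
post-snowmelt acquisitions in the growing season (Jun 15–Aug 31) and
pre-snowfall acquisitions in senescence (Sep 15–Nov 30). Cloud-, shadow-
or snow-masked observations are *ineligible*, not zero-scored, so a masked
value can never enter a composite; this is asserted by a provenance audit.
Score ties break by day-of-year proximity to the target, then the later
acquisition, making composites deterministic. The exact criterion set and
weights used operationally vary between archives; the defaults here are
substitutes chosen to be monotone and bounded, and every number is exposed
in configuration.

## Retrospective training via the Z-statistic

The reference cartography (polygons or a class grid, epoch `T1`) is first
cleaned to the sensor lattice: patches under the minimum mapping unit of
one 30 m pixel (900 m², strict `<`) and patches narrower than 30 m are
removed (the width test erodes by half the minimum width shaved by 0.1% so
an exactly-minimum patch survives), and the remainder is rasterized by the
cell-centre rule.

Per class `c` and predictor `b`, the reference epoch yields a signature
(mean `mu_cb`, sample sd `sigma_cb`). For any target year, a pixel of
mapped class `c` with predictor vector `x` gets

    Z = sqrt( sum_b ((x_b - mu_cb) / sigma_cb)^2 )

i.e. independently standardized deviations with no covariance term — the
form used in the cross-correlation-analysis change-detection literature; a
Mahalanobis variant is deliberately out of scope. Predictors that are
constant within a class (sd at or below 1e-9 relative tolerance) are
dropped from that class's Z rather than failing the run. Per class and
year, pixels at or below the `retention_q` quantile of Z (default 0.5, the
inner half) are retained as "pure", unchanged training samples; tail
pixels — likely mixed or changed since `T1` — are excluded. Whether one
global or per-class retention quantile is preferable is an open question;
the default is one global quantile, configurable. Topographic and
geological predictors enter every year unchanged; a canopy-height model
participates only in years it is supplied for (typically `T1`), and the
signature is recomputed on the common predictor set for other years.

## Predictor selection

Three stages, each subsetting the previous: (1) one-vs-rest ROC AUC per
predictor and class, direction-free (`max(AUC, 1-AUC)`), keeping
predictors reaching 0.75 for at least one class; (2) a shadow-feature
(Boruta-style) test — each of up to 100 runs appends a permuted copy of
every predictor, fits a random forest, and counts a hit when a real
predictor's Gini importance beats the best shadow; a two-sided binomial
test at alpha 0.01 confirms or rejects, leftover tentatives resolved by
median importance against the median best-shadow, ties to rejection;
(3) greedy Kendall tau-b pruning at |tau| > 0.9, dropping the member of
the worst pair with the lower Boruta importance (falling back to best
per-class AUC), on a seeded subsample of at most 10,000 rows.

## Ensemble classification and the class hierarchy

Per year, five random forests are trained on the same pure-pixel table
with member seeds spawned deterministically from one master seed; members
differ only in their random streams. Hyperparameters default to the tuned
values used operationally — 100 trees, `mtry` 16 (clamped to the predictor
count with a warning), minimum node size 4, bootstrap sample fraction
0.51 — and a tuning hook exists but re-tuning is not re-implemented.
Prediction is per-pixel majority vote; ties break by the higher mean
ensemble class probability, then the lower class code. A pixel missing any
predictor is nodata.

Habitats are classified hierarchically: each vegetated land-cover class
(broadleaved 4, coniferous 5, grassland 6, shrubland 7) has its own
ensemble trained only on that class's habitat labels, applied only to
pixels the land-cover map assigned to it. Non-vegetated classes (rocks,
snow/glaciers, water, wetland) carry no habitat label. The parent of every
emitted habitat label therefore equals the pixel's land-cover label by
construction, and the implementation asserts it. Wetland is classified at
level 1 but is conventionally excluded from trend reporting because its
delineation from moderate-resolution imagery is unreliable.

## Temporal filtering, aggregation and change detection

Three rules run in a fixed order over each pixel's annual label sequence:

1. **Gap filling** — a missing year takes the modal class of up to three
   preceding and three following non-missing years, computed
   simultaneously from the original labels; mode ties go to the nearest
   neighbour, the earlier one at equal distance; an all-missing window
   stays missing.
2. **Water persistence** — a pixel labelled water for *strictly more than
   half* the series becomes water throughout (20 of 39 years flips, 19
   does not).
3. **Singleton removal** — classes occurring in exactly one year are
   absorbed into the modal class among the non-singleton classes (ties to
   the lower code); if every class is a singleton the sequence is left
   unchanged, which keeps the rule idempotent.

The chain is a fixed point of itself on gap-free sequences (verified
exhaustively for all 3-class sequences up to length 6). Note the water
rule and singleton rule can interact when water is itself a singleton
candidate; the fixed order resolves this deterministically.

Cleaned series are aggregated to roughly decadal windows (default
1985–1995, 1995–2005, 2005–2015, 2015–2023; any window list is accepted
and `AggregationScheme.evenly` splits arbitrary year ranges). Windows are
half-open `[start, end)` except the last (closed), so shared boundary
years are never double-counted. Within a window each pixel takes its modal
class, ties resolved to the class observed in the latest window year.

Aggregated trajectories are typed: **stable** (one class throughout),
**transition** (exactly one change point and exactly two classes — a
unidirectional shift), **mixed** (anything else). The three types
partition all gap-free pixels; of the 81 three-class sequences of length
four, exactly 3 are stable, 18 transition and 60 mixed. Typing uses the
aggregated series by default (the annual series is available via
configuration). Class-to-class change is tallied over transition-typed
pixels only, in hectares (0.09 ha per 30 m pixel) and percent of changed
area, with pairs under 1% excluded from the report but kept in the raw
matrix. Area-change rates are ordinary-least-squares slopes of annual
class area against year (ha yr⁻¹; an endpoint-difference option exists),
optionally within region masks and altitudinal belts (mountain 1400–1900 m,
sub-alpine 1900–2300 m, alpine 2300–2700 m, nival 2700–4000 m; boundaries
belong to the upper belt). Greening and climate trends use an OLS slope
with a two-sided t-test and the usual significance stars (* p<0.05,
** p<0.01, *** p<0.001); a Theil–Sen/Mann–Kendall alternative is a
configuration option, not the default. A perfectly collinear series gets
p = 0 for a non-zero slope rather than a 0/0 artefact.

## Accuracy assessment

Confusion matrices are oriented rows = predicted, columns = reference, and
every output states so. Overall metrics: overall accuracy, balanced
accuracy (mean per-class (recall+specificity)/2), Cohen's kappa, and
weighted accuracy — a weighted mean of per-class recall whose default
weights are inverse reference prevalence, deliberately up-weighting rare
habitats; the operational weighting scheme this substitutes is not
published, so the weights are user-overridable and documented as a
default. Per-class metrics: producer's and user's accuracy, F1, and the
true skill statistic (recall + specificity − 1). Undefined quantities
(empty margins, single-class kappa) propagate as missing, never as 0.

Patch structure uses 8-connected components and 4-connected edges
(both conventional in landscape ecology, both configurable): patch count,
mean patch area, total edge length at 30 m per face, and the
circle-normalized shape index P/(2·sqrt(pi·A)) (1 for a disc, ~1.13 for a
square). Accuracy–structure association is the Pearson correlation across
classes, pairwise-complete, undefined below three complete pairs.

## The synthetic study

The generator emulates the inputs the real workflow consumes, with all
randomness flowing from one master seed through named substreams so
stages can be varied independently.

- **Terrain**: a south-facing ramp spanning 600–4000 m plus a broad
  correlated relief field (Gaussian-smoothed noise, sigma 10 px, 4% of the
  range) keeping local slopes in the range a 30 m alpine DTM shows.
- **Land cover**: elevation-zoned with noisy boundaries — broadleaved
  below ~1500 m, conifers to ~2200 m, grassland with interleaved shrubland
  patches to ~2750 m, rocks, then perennial snow; a valley lake with a
  wetland fringe. Habitats partition each vegetated parent through a
  second correlated field (three habitats per parent).
- **Spectra**: per-class six-band means with Gaussian sensor noise
  (default sd 0.01 reflectance) and a Gaussian seasonal NIR/red phenology
  pulse (deciduous amplitude 0.08, grassland 0.06, shrubland 0.05,
  conifers 0.02). Habitat signatures offset the parent mean by a
  configurable separation (default 0.03 on NIR/SWIR1).
- **Illumination**: reflectance scales with (cos i + d)/(cos theta_z + d),
  d = 0.25 a diffuse-skylight term, so shaded slopes darken strongly but
  not to zero; the factor is band-independent, which is what makes the
  terrain correction and index invariance exercisable.
- **Occlusion**: smoothed-noise cloud blobs at a configurable scene
  fraction (default 0.1) with offset shadows; seasonal snow above a
  day-of-year-dependent snowline with elevation jitter. Masks match the
  rendered contamination exactly. Perennial snow/ice is scene content, not
  mask.
- **Change**: contiguous patches flipped from a given year onward, with a
  ledger recording exactly the flipped pixels; later overlapping plantings
  win and the ledger reflects final state.

What the generator does *not* emulate: sensor-specific band responses and
cross-sensor calibration drift, atmospheric variability beyond a scalar
opacity, mixed pixels and gradual fractional-cover change, mask errors
(masks are perfect by construction), and reference-map labelling errors.
Passing the synthetic recovery tests therefore demonstrates the internal
consistency of the workflow — compositing, screening, classification and
change accounting do not distort a signal they are given — not performance
on real archives, where mask quality and mixed pixels dominate the error
budget.

## Problem sizes and numerical choices

The end-to-end validation runs a 128×128 world for ten years with three
scenes per season, training tables capped at 1,500 rows per year by
stratified subsampling with at least 50 rows per present class — rare
classes (water, wetland) would otherwise all but vanish from proportional
samples. These sizes are the package's default desk-scale study; all are
configuration values. Other numerical choices: sample sd uses ddof 1;
class-signature degeneracy uses a 1e-9 relative tolerance; quantile cuts
use the default linear interpolation, and retention keeps Z less than or
equal to the cut; normalized indices return nodata on zero denominators;
all tie-breaks (votes, modes, aggregation, pruning) are documented above
and deterministic.

## Known limitations

- The additive cosine correction under-corrects extreme slopes; residual
  illumination error is the dominant confusion source between spectrally
  close classes (shrubland vs conifers) on steep terrain, in synthetic and
  real data alike.
- The Z-screen assumes the reference epoch's within-class predictor
  distribution is stationary up to the retained quantile; strong
  class-wide phenological anomalies in a year shrink that year's training
  set rather than biasing it.
- Trajectory typing on short aggregated series (two windows) cannot
  distinguish a transition from a single misclassified window; longer
  series sharpen the partition.
- The hierarchy never revisits the land-cover decision: a level-1 error
  forces a wrong habitat family by construction. This is the price of the
  guarantee that habitat labels never contradict land cover.
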