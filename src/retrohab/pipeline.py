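"""End-to-end orchestration of the mapping workflow.

The library surface is :func:`run_pipeline`, which takes scene stacks, a
terrain model and a reference map and carries them through terrain
correction, seasonal BAP compositing, retrospective training extraction,
ensemble classification, temporal filtering, aggregation and change/
accuracy summaries.  The CLI stages in :mod:`retrohab.cli` are thin
wrappers that persist each step's products to a run directory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import EnsembleModel, RfHyperparams, hierarchical_classify, predict_majority, train_ensemble
from .compositing import (
    BapCriteria,
    SceneStack,
    SeasonalComposite,
    compose_bap,
    compute_illumination,
    improved_cosine_correct,
    spectral_index,
    terrain_from_dtm,
)
from .core import ClassMapSeries, Grid, ValidationError
from .retrotruth import ReferenceMap, build_annual_training
from .selection import select_predictors
from .temporal import (
    AggregationScheme,
    apply_rules_series,
    change_rate,
    decadal_aggregate,
    trajectory_type_map,
    transition_matrix,
    trend,
)
from .validate import class_metrics, confusion, overall_metrics

__all__ = ["PipelineResult", "run_pipeline", "correct_scenes", "build_predictor_stacks", "stratified_subsample"]


@dataclass
class PipelineResult:
    """Everything the pipeline produced, ready for reporting or export."""

    years: list[int]
    predictor_stacks: dict[int, dict[str, Grid]]
    training: dict[int, pd.DataFrame]
    models: dict[int, EnsembleModel]
    raw_series: ClassMapSeries
    clean_series: ClassMapSeries
    aggregated: ClassMapSeries
    trajectory_types: Grid
    transitions: object
    change_rates: dict[int, float]
    metrics: dict[str, float] = field(default_factory=dict)
    per_class: pd.DataFrame | None = None
    l2_maps: dict[int, Grid] = field(default_factory=dict)
    ndvi_trends: pd.DataFrame | None = None
    selected_predictors: list[str] | None = None


def correct_scenes(scenes: list[SceneStack], terrain) -> list[SceneStack]:
    """Terrain-correct every band of every scene in place (improved cosine)."""
    for scene in scenes:
        cos_i = compute_illumination(terrain, scene.solar_zenith, scene.solar_azimuth)
        land = ~scene.cloud_mask & ~scene.shadow_mask & ~scene.snow_mask
        for name in list(scene.bands):
            scene.bands[name] = improved_cosine_correct(
                scene.bands[name], cos_i, valid=land
            )
    return scenes


def build_predictor_stacks(
    scenes: list[SceneStack],
    dtm: Grid,
    years: list[int],
    criteria: BapCriteria | None = None,
    indices: tuple[str, ...] = ("ndvi", "ndwi", "nbr", "ndmi", "ndsi"),
    extra_static: dict[str, Grid] | None = None,
) -> tuple[dict[int, dict[str, Grid]], dict[tuple[int, str], SeasonalComposite]]:
    """Seasonal composites and per-year predictor stacks.

    Per year the stack holds both seasons' reflectance bands and spectral
    indices, plus static topographic predictors (elevation, slope,
    northness) which are assumed stable over time.
    """
    criteria = criteria or BapCriteria()
    terrain = terrain_from_dtm(dtm)
    static = {
        "elevation": dtm,
        "slope": terrain.slope,
        "northness": dtm.like(np.cos(terrain.aspect.values), nodata=None),
    }
    static.update(extra_static or {})
    stacks: dict[int, dict[str, Grid]] = {}
    composites: dict[tuple[int, str], SeasonalComposite] = {}
    prefix = {"growing": "gs", "senescence": "sen"}
    for year in years:
        stack: dict[str, Grid] = {}
        for season in ("growing", "senescence"):
            comp = compose_bap(scenes, year, season, criteria)
            composites[(year, season)] = comp
            if not comp.bands:
                continue
            for name, grid in comp.bands.items():
                stack[f"{prefix[season]}_{name}"] = grid
            for idx in indices:
                stack[f"{prefix[season]}_{idx}"] = spectral_index(comp, idx)
        stack.update(static)
        stacks[year] = stack
    return stacks, composites


def stratified_subsample(
    table: pd.DataFrame, max_rows: int, seed: int, min_per_class: int = 50
) -> pd.DataFrame:
    """Cap a training table at ``max_rows``, keeping every class represented."""
    if len(table) <= max_rows:
        return table
    frac = max_rows / len(table)
    parts = []
    for _, grp in table.groupby("label"):
        take = max(min(min_per_class, len(grp)), int(round(len(grp) * frac)))
        parts.append(grp.sample(min(take, len(grp)), random_state=seed))
    return pd.concat(parts, ignore_index=True)


def run_pipeline(
    scenes: list[SceneStack],
    dtm: Grid,
    reference: ReferenceMap,
    years: list[int],
    criteria: BapCriteria | None = None,
    retention_q: float = 0.5,
    rf_params: RfHyperparams = RfHyperparams(),
    master_seed: int = 0,
    max_train_rows: int = 1500,
    n_windows: int = 2,
    feature_selection: bool = False,
    classify_l2: bool = False,
    aggregation: AggregationScheme | None = None,
    truth_series: ClassMapSeries | None = None,
) -> PipelineResult:
    """Run the whole workflow in memory and summarise its outcome.

    When ``truth_series`` is given (synthetic experiments), accuracy
    metrics of the cleaned annual maps against the truth are attached.
    """
    terrain = terrain_from_dtm(dtm)
    scenes = correct_scenes(scenes, terrain)
    stacks, _ = build_predictor_stacks(scenes, dtm, years, criteria)
    training = build_annual_training(reference, stacks, retention_q=retention_q)

    selected: list[str] | None = None
    if feature_selection:
        t1 = reference.reference_year
        report = select_predictors(
            stratified_subsample(training[t1], max_train_rows, master_seed),
            [c for c in training[t1].columns if c not in ("row", "col", "year", "label", "z")],
            rf_params={"n_estimators": 50, "max_samples": rf_params.sample_fraction},
            seed=master_seed,
        )
        selected = report.final or report.screened

    models: dict[int, EnsembleModel] = {}
    maps: list[Grid] = []
    kept_years: list[int] = []
    for year in years:
        table = training.get(year)
        if table is None or table.empty or table["label"].nunique() < 2:
            warnings.warn(f"year {year}: unusable training table; year skipped")
            continue
        predictors = selected or [
            c for c in table.columns if c not in ("row", "col", "year", "label", "z")
        ]
        table = stratified_subsample(table, max_train_rows, master_seed + year)
        model = train_ensemble(
            table, predictors, params=rf_params, master_seed=master_seed + year
        )
        models[year] = model
        maps.append(predict_majority(model, stacks[year]))
        kept_years.append(year)
    if not kept_years:
        raise ValidationError("no year produced a classification")

    raw_series = ClassMapSeries(
        years=kept_years, maps=maps, level="L1", legend=reference.legend
    )
    clean_series = apply_rules_series(raw_series)
    scheme = aggregation or AggregationScheme.evenly(kept_years, n_windows)
    aggregated = decadal_aggregate(clean_series, scheme)
    traj_types = trajectory_type_map(aggregated)

    mask = np.asarray(traj_types.values) == 2  # transition-typed pixels
    transitions = transition_matrix(aggregated.maps[0], aggregated.maps[-1], mask)

    rates: dict[int, float] = {}
    for c in sorted(set(np.unique(np.stack([m.values for m in clean_series.maps]))) - {0}):
        rates[int(c)] = change_rate(clean_series, int(c))

    result = PipelineResult(
        years=kept_years,
        predictor_stacks=stacks,
        training=training,
        models=models,
        raw_series=raw_series,
        clean_series=clean_series,
        aggregated=aggregated,
        trajectory_types=traj_types,
        transitions=transitions,
        change_rates=rates,
        selected_predictors=selected,
    )

    if classify_l2:
        result.l2_maps = _classify_l2(result, reference, stacks, rf_params, master_seed, max_train_rows)

    if truth_series is not None:
        pred = np.concatenate([np.asarray(m.values).ravel() for m in clean_series.maps])
        truth_by_year = dict(zip(truth_series.years, truth_series.maps))
        ref = np.concatenate(
            [np.asarray(truth_by_year[y].values).ravel() for y in kept_years]
        )
        cm = confusion(pred, ref)
        result.metrics = overall_metrics(cm)
        result.per_class = class_metrics(cm)

    # greening proxy: per-class mean growing-season NDVI trend
    result.ndvi_trends = _ndvi_trends(clean_series, stacks)
    return result


def _classify_l2(
    result: PipelineResult,
    reference: ReferenceMap,
    stacks: dict[int, dict[str, Grid]],
    rf_params: RfHyperparams,
    master_seed: int,
    max_train_rows: int,
) -> dict[int, Grid]:
    """Hierarchical habitat maps for every classified year."""
    if reference.l2 is None or reference.legend is None:
        return {}
    legend = reference.legend
    l2_training = build_annual_training(reference, stacks, level="L2")
    out: dict[int, Grid] = {}
    for i, year in enumerate(result.years):
        table = l2_training.get(year)
        if table is None or table.empty:
            continue
        l2_models: dict[int, EnsembleModel] = {}
        for parent in legend.vegetation_l1:
            children = set(legend.children_of(parent))
            sub = table[table["label"].isin(children)]
            if sub.empty or sub["label"].nunique() < 2:
                continue
            predictors = result.selected_predictors or [
                c for c in sub.columns if c not in ("row", "col", "year", "label", "z")
            ]
            sub = stratified_subsample(sub, max_train_rows // 2, master_seed + year + parent)
            l2_models[parent] = train_ensemble(
                sub, predictors, params=rf_params,
                master_seed=master_seed + 1000 + year + parent,
                level="L2", parent_class=parent,
            )
        if l2_models:
            out[year] = hierarchical_classify(
                result.clean_series.maps[i], l2_models, stacks[year], legend=legend
            )
    return out


def _ndvi_trends(series: ClassMapSeries, stacks: dict[int, dict[str, Grid]]) -> pd.DataFrame:
    records = []
    classes = sorted(set(np.unique(np.stack([m.values for m in series.maps]))) - {0})
    ndvi_by_year = {
        y: stacks[y]["gs_ndvi"].values for y in series.years if "gs_ndvi" in stacks.get(y, {})
    }
    for c in classes:
        values = []
        yrs = []
        for y, m in zip(series.years, series.maps):
            if y not in ndvi_by_year:
                continue
            sel = np.asarray(m.values) == c
            nd = ndvi_by_year[y]
            ok = sel & np.isfinite(nd)
            if ok.any():
                values.append(float(np.mean(nd[ok])))
                yrs.append(y)
        if len(values) >= 3:
            slope, p, stars = trend(values, yrs)
            records.append({"class": c, "slope_per_year": slope, "p_value": p, "stars": stars})
    return pd.DataFrame(records)
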