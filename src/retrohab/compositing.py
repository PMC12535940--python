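"""Seasonal best-available-pixel (BAP) compositing of optical scene stacks.

Each acquisition is a :class:`SceneStack` of co-registered reflectance bands
with cloud/cloud-shadow/snow masks and solar geometry.  Scenes are
terrain-corrected ("improved cosine"), filtered by whole-scene cloud cover,
and every unmasked observation is scored with six weighted criteria
(sensor, proximity to a target day-of-year, distance to cloud, distance to
snow, scene snow-free fraction, atmospheric opacity).  Per pixel and season
the highest-scoring observation wins, yielding one growing-season and one
senescence composite per year, from which spectral indices are computed.

The snow-related criteria favour observations acquired after snowmelt
(growing season) and before early snowfall (senescence), which matters in
alpine terrain where snow duration varies strongly with elevation.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import Grid, ValidationError

__all__ = [
    "SceneStack",
    "TerrainModel",
    "BapCriteria",
    "SeasonalComposite",
    "terrain_from_dtm",
    "compute_illumination",
    "improved_cosine_correct",
    "filter_scenes",
    "score_observation",
    "score_scene",
    "compose_bap",
    "spectral_index",
    "SEASON_WINDOWS",
    "INDEX_BANDS",
]

BAND_NAMES = ("blue", "green", "red", "nir", "swir1", "swir2")

#: Season windows as ((start_month, start_day), (end_month, end_day)), inclusive.
SEASON_WINDOWS = {
    "growing": ((6, 15), (8, 31)),
    "senescence": ((9, 15), (11, 30)),
}


@dataclass
class SceneStack:
    """One acquisition: reflectance bands, masks and metadata."""

    bands: dict[str, Grid]
    cloud_mask: np.ndarray
    shadow_mask: np.ndarray
    snow_mask: np.ndarray
    sensor_id: str
    date: _dt.date
    solar_zenith: float
    solar_azimuth: float
    scene_cloud_pct: float = 0.0
    scene_snowfree_pct: float = 100.0
    opacity: float | None = None

    def __post_init__(self) -> None:
        shape = next(iter(self.bands.values())).shape
        for name, g in self.bands.items():
            if g.shape != shape:
                raise ValidationError(f"band {name} shape mismatch")
        for m in (self.cloud_mask, self.shadow_mask, self.snow_mask):
            if m.shape != shape:
                raise ValidationError("mask geometry must match bands")
        if not 0.0 < self.solar_zenith < 90.0:
            raise ValidationError("solar zenith must lie in (0, 90) degrees")

    @property
    def doy(self) -> int:
        return self.date.timetuple().tm_yday

    def valid_mask(self) -> np.ndarray:
        """Pixels carrying usable reflectance in every band."""
        mask = np.ones(self.cloud_mask.shape, dtype=bool)
        for g in self.bands.values():
            mask &= g.valid_mask()
        return mask


@dataclass
class TerrainModel:
    """Elevation with derived slope/aspect (radians, aspect clockwise from N)."""

    elevation: Grid
    slope: Grid
    aspect: Grid


def terrain_from_dtm(dtm: Grid) -> TerrainModel:
    """Derive slope and aspect from elevation by central differences."""
    z = np.asarray(dtm.values, dtype=float)
    px = dtm.transform.pixel_size
    dz_drow, dz_dcol = np.gradient(z, px)
    dz_dnorth = -dz_drow  # rows increase southwards
    slope = np.arctan(np.hypot(dz_dcol, dz_dnorth))
    # azimuth of the downslope direction, clockwise from north
    aspect = np.mod(np.arctan2(-dz_dcol, -dz_dnorth), 2 * np.pi)
    return TerrainModel(
        elevation=dtm,
        slope=dtm.like(slope, nodata=None),
        aspect=dtm.like(aspect, nodata=None),
    )


def compute_illumination(
    terrain: TerrainModel, solar_zenith: float, solar_azimuth: float
) -> Grid:
    """Illumination angle cosine on sloped terrain.

    cos i = cos(theta_z) cos(S) + sin(theta_z) sin(S) cos(phi - A), clamped
    to [-1, 1]; theta_z is the solar zenith and phi the solar azimuth in
    degrees, S/A the local slope/aspect in radians.
    """
    if not 0.0 < solar_zenith < 90.0:
        raise ValidationError("solar zenith must lie in (0, 90) degrees")
    tz = np.deg2rad(solar_zenith)
    phi = np.deg2rad(solar_azimuth)
    s = terrain.slope.values
    a = terrain.aspect.values
    cos_i = np.cos(tz) * np.cos(s) + np.sin(tz) * np.sin(s) * np.cos(phi - a)
    return terrain.elevation.like(np.clip(cos_i, -1.0, 1.0), nodata=None)


def improved_cosine_correct(
    band: Grid, cos_i: Grid, valid: np.ndarray | None = None
) -> Grid:
    """Improved-cosine topographic correction of one reflectance band.

    L' = L + L * (<cos i> - cos i) / <cos i>, where <cos i> is the scene
    mean illumination over valid (unmasked) land pixels.  Pixels brighter
    than the scene would be under flat illumination are darkened and vice
    versa; a flat scene (constant cos i) is left untouched.
    """
    mask = band.valid_mask()
    if valid is not None:
        mask &= valid
    if not mask.any():
        raise ValidationError("no valid pixels to compute mean illumination")
    mean_ci = float(np.mean(cos_i.values[mask]))
    if mean_ci <= 0:
        raise ArithmeticError(f"mean illumination must be positive, got {mean_ci:.4f}")
    L = np.asarray(band.values, dtype=float)
    corrected = L + L * (mean_ci - cos_i.values) / mean_ci
    out = np.where(mask, corrected, L)
    if band.nodata is not None:
        out = np.where(band.values == band.nodata, band.nodata, out)
    return band.like(out)


def filter_scenes(scenes: list[SceneStack], threshold: float = 70.0) -> list[SceneStack]:
    """Drop scenes whose whole-scene cloud cover strictly exceeds ``threshold`` %."""
    return [s for s in scenes if s.scene_cloud_pct <= threshold]


@dataclass
class BapCriteria:
    """Six-criterion scoring configuration for BAP compositing.

    ``weights`` must be non-negative and sum to 1.  Distance criteria are
    smooth sigmoids through 0.5 at their midpoint, saturating at 1 beyond
    twice the midpoint.  The day-of-year criterion is a Gaussian around the
    per-season target day.
    """

    weights: dict[str, float] = field(
        default_factory=lambda: {
            "sensor": 1 / 6,
            "doy": 1 / 6,
            "dist_cloud": 1 / 6,
            "dist_snow": 1 / 6,
            "scene_snowfree": 1 / 6,
            "opacity": 1 / 6,
        }
    )
    target_doy: dict[str, int] = field(
        default_factory=lambda: {"growing": 213, "senescence": 288}  # Aug 1 / Oct 15
    )
    sigma_doy: float = 15.0
    dist_cloud_midpoint: float = 10.0
    dist_snow_midpoint: float = 10.0
    sensor_scores: dict[str, float] = field(default_factory=dict)
    season_windows: dict = field(default_factory=lambda: dict(SEASON_WINDOWS))
    cloud_threshold: float = 70.0

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValidationError("criterion weights must be non-negative")
        if abs(sum(self.weights.values()) - 1.0) > 1e-9:
            raise ValidationError("criterion weights must sum to 1")

    def in_window(self, date: _dt.date, season: str) -> bool:
        (m0, d0), (m1, d1) = self.season_windows[season]
        start = _dt.date(date.year, m0, d0)
        end = _dt.date(date.year, m1, d1)
        return start <= date <= end


def _sigmoid_distance(d: np.ndarray | float, midpoint: float) -> np.ndarray | float:
    """Smoothstep sigmoid: 0 at distance 0, 0.5 at the midpoint, 1 beyond 2x."""
    s = np.clip(np.asarray(d, dtype=float) / (2.0 * midpoint), 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def _doy_score(doy: int, target: int, sigma: float) -> float:
    return float(np.exp(-((doy - target) ** 2) / (2.0 * sigma**2)))


def _scalar_scores(scene: SceneStack, criteria: BapCriteria, season: str) -> dict[str, float]:
    opacity = 1.0 if scene.opacity is None else float(np.clip(1.0 - scene.opacity, 0.0, 1.0))
    return {
        "sensor": float(criteria.sensor_scores.get(scene.sensor_id, 1.0)),
        "doy": _doy_score(scene.doy, criteria.target_doy[season], criteria.sigma_doy),
        "scene_snowfree": scene.scene_snowfree_pct / 100.0,
        "opacity": opacity,
    }


def score_observation(
    scene: SceneStack,
    pixel: tuple[int, int],
    criteria: BapCriteria,
    dist_to_cloud: float,
    dist_to_snow: float,
    season: str = "growing",
) -> float | None:
    """Score one candidate observation; ``None`` if the pixel is ineligible.

    Cloud-, shadow- or snow-masked pixels are ineligible rather than
    zero-scored, so they can never win a composite slot.
    """
    r, c = pixel
    if scene.cloud_mask[r, c] or scene.shadow_mask[r, c] or scene.snow_mask[r, c]:
        return None
    if not scene.valid_mask()[r, c]:
        return None
    parts = _scalar_scores(scene, criteria, season)
    parts["dist_cloud"] = float(_sigmoid_distance(dist_to_cloud, criteria.dist_cloud_midpoint))
    parts["dist_snow"] = float(_sigmoid_distance(dist_to_snow, criteria.dist_snow_midpoint))
    return sum(criteria.weights[k] * parts[k] for k in criteria.weights)


def _mask_distance(mask: np.ndarray) -> np.ndarray:
    """Per-pixel distance (px) to the nearest masked cell; inf if none masked."""
    if not mask.any():
        return np.full(mask.shape, np.inf)
    return ndimage.distance_transform_edt(~mask)


def score_scene(
    scene: SceneStack, criteria: BapCriteria, season: str
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised scores for every pixel of one scene.

    Returns ``(scores, eligible)``; scores are undefined where not eligible.
    """
    eligible = (
        ~scene.cloud_mask & ~scene.shadow_mask & ~scene.snow_mask & scene.valid_mask()
    )
    parts = _scalar_scores(scene, criteria, season)
    scalar = sum(
        criteria.weights[k] * parts[k]
        for k in ("sensor", "doy", "scene_snowfree", "opacity")
    )
    d_cloud = _mask_distance(scene.cloud_mask | scene.shadow_mask)
    d_snow = _mask_distance(scene.snow_mask)
    scores = (
        scalar
        + criteria.weights["dist_cloud"] * _sigmoid_distance(d_cloud, criteria.dist_cloud_midpoint)
        + criteria.weights["dist_snow"] * _sigmoid_distance(d_snow, criteria.dist_snow_midpoint)
    )
    return scores, eligible


@dataclass
class SeasonalComposite:
    """Per-year, per-season BAP mosaic with per-pixel provenance."""

    year: int
    season: str
    bands: dict[str, Grid]
    provenance: Grid
    scene_dates: list[_dt.date]
    indices: dict[str, Grid] = field(default_factory=dict)


def compose_bap(
    scenes: list[SceneStack],
    year: int,
    season: str,
    criteria: BapCriteria | None = None,
) -> SeasonalComposite:
    """Build one seasonal composite by per-pixel argmax of observation scores.

    Ties are broken by day-of-year proximity to the seasonal target, then by
    the later acquisition date, making the composite deterministic.
    """
    criteria = criteria or BapCriteria()
    candidates = [
        s for s in scenes if s.date.year == year and criteria.in_window(s.date, season)
    ]
    candidates = filter_scenes(candidates, criteria.cloud_threshold)
    if not candidates:
        warnings.warn(f"no eligible scenes for {year} {season}; composite is empty")
        return SeasonalComposite(
            year=year, season=season, bands={},
            provenance=Grid(np.full((0, 0), -1, dtype=np.int32), nodata=-1),
            scene_dates=[],
        )

    shape = candidates[0].cloud_mask.shape
    template = next(iter(candidates[0].bands.values()))
    target = criteria.target_doy[season]

    best_score = np.full(shape, -np.inf)
    best_doydist = np.full(shape, np.inf)
    best_dateord = np.full(shape, -np.inf)
    winner = np.full(shape, -1, dtype=np.int32)

    for idx, scene in enumerate(candidates):
        scores, eligible = score_scene(scene, criteria, season)
        doydist = abs(scene.doy - target)
        dateord = scene.date.toordinal()
        better = scores > best_score
        tie = scores == best_score
        better |= tie & (doydist < best_doydist)
        better |= tie & (doydist == best_doydist) & (dateord > best_dateord)
        take = eligible & better
        best_score[take] = scores[take]
        best_doydist[take] = doydist
        best_dateord[take] = dateord
        winner[take] = idx

    band_names = list(candidates[0].bands)
    out_bands: dict[str, Grid] = {}
    for name in band_names:
        stack = np.stack([np.asarray(s.bands[name].values, dtype=float) for s in candidates])
        vals = np.full(shape, np.nan)
        rows, cols = np.nonzero(winner >= 0)
        vals[rows, cols] = stack[winner[rows, cols], rows, cols]
        out_bands[name] = template.like(vals, nodata=None)

    return SeasonalComposite(
        year=year,
        season=season,
        bands=out_bands,
        provenance=template.like(winner, nodata=-1),
        scene_dates=[s.date for s in candidates],
    )


#: Normalised-difference index registry: name -> (plus band, minus band).
INDEX_BANDS = {
    "ndvi": ("nir", "red"),
    "ndwi": ("green", "nir"),
    "nbr": ("nir", "swir2"),
    "ndsi": ("green", "swir1"),
    "ndmi": ("nir", "swir1"),
}


def spectral_index(composite: SeasonalComposite, name: str) -> Grid:
    """Compute a registered normalised-difference index; cached on the composite.

    Zero denominators become nodata (NaN) rather than propagating infinities.
    """
    name = name.lower()
    if name not in INDEX_BANDS:
        raise ValidationError(f"unknown spectral index: {name!r}")
    plus, minus = INDEX_BANDS[name]
    for b in (plus, minus):
        if b not in composite.bands:
            raise ValidationError(f"index {name} requires band {b!r}")
    a = np.asarray(composite.bands[plus].values, dtype=float)
    b = np.asarray(composite.bands[minus].values, dtype=float)
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom != 0, (a - b) / denom, np.nan)
    grid = composite.bands[plus].like(vals, nodata=None)
    composite.indices[name] = grid
    return grid
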