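"""Synthetic alpine worlds: terrain, land cover, scene stacks, change ledgers.

The generator emulates what the real pipeline consumes — an
elevation-structured landscape (broadleaved forest low, conifers mid,
grassland/shrubland above the treeline, rocks and perennial snow on top,
a lake and a small wetland), per-class spectral signatures with seasonal
phenology, multiplicative illumination on slopes, cloud/snow occlusion
blobs with matching masks, sensor noise, and a ledger that records every
planted class transition — so every stage of the workflow is testable
without any downloads.

All randomness flows from one master seed through named substreams
(landscape, phenology, noise, clouds, changes), so stages can be varied
independently while staying reproducible.
"""

from __future__ import annotations

import datetime as _dt
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .compositing import BAND_NAMES, SceneStack, terrain_from_dtm, compute_illumination
from .core import Grid, Legend, ValidationError, default_legend

__all__ = [
    "SyntheticWorld",
    "ChangeEvent",
    "generate_landscape",
    "generate_world",
    "plant_changes",
    "render_scenes",
]

# Mean surface reflectance per L1 class over (blue, green, red, nir, swir1, swir2).
SPECTRA: dict[int, tuple[float, ...]] = {
    1: (0.18, 0.20, 0.22, 0.24, 0.28, 0.26),  # rocks
    2: (0.90, 0.88, 0.85, 0.75, 0.20, 0.15),  # snow and glaciers
    3: (0.05, 0.06, 0.04, 0.02, 0.01, 0.01),  # water
    4: (0.030, 0.060, 0.040, 0.45, 0.22, 0.12),  # broadleaved
    5: (0.025, 0.050, 0.035, 0.28, 0.14, 0.08),  # coniferous
    6: (0.040, 0.080, 0.070, 0.38, 0.26, 0.15),  # grassland
    7: (0.035, 0.065, 0.048, 0.31, 0.19, 0.10),  # shrubland
    8: (0.040, 0.070, 0.050, 0.30, 0.13, 0.06),  # wetland
}

# Seasonal NIR phenology: (amplitude, peak day-of-year); red moves opposite
# at a quarter of the amplitude.  Evergreens barely move.
PHENOLOGY: dict[int, tuple[float, int]] = {
    4: (0.08, 200),
    5: (0.02, 200),
    6: (0.06, 195),
    7: (0.05, 205),
    8: (0.04, 195),
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(stream.encode())])
    )


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = field.std()
    return field / sd if sd > 0 else field


@dataclass
class ChangeEvent:
    year: int
    from_class: int
    to_class: int
    pixels: list[tuple[int, int]]


@dataclass
class SyntheticWorld:
    seed: int
    dtm: Grid
    years: list[int]
    true_l1: dict[int, np.ndarray]
    true_l2: dict[int, np.ndarray]
    legend: Legend
    ledger: list[ChangeEvent] = field(default_factory=list)
    l2_separation: float = 0.03

    @property
    def shape(self) -> tuple[int, int]:
        return self.dtm.shape

    def l1_series_maps(self) -> list[Grid]:
        return [self.dtm.like(self.true_l1[y].astype(np.uint16), nodata=0) for y in self.years]


def generate_landscape(
    seed: int,
    shape: tuple[int, int] = (128, 128),
    elevation_range: tuple[float, float] = (600.0, 4000.0),
    legend: Legend | None = None,
) -> tuple[Grid, np.ndarray, np.ndarray]:
    """Static part of a world: terrain plus the initial L1/L2 maps.

    Elevation is a smooth south-to-north ramp plus correlated noise; L1
    classes follow elevation with noisy boundaries, grassland and
    shrubland interleave above the treeline, and a lake plus a fringing
    wetland sit in the valley bottom.  L2 habitats partition each
    vegetated parent with a second correlated field.
    """
    if min(shape) < 30:
        raise ValidationError("landscape must be at least 30x30")
    legend = legend or default_legend()
    rng = _rng(seed, "landscape")
    h, w = shape
    lo, hi = elevation_range
    ramp = np.linspace(1.0, 0.0, h)[:, None] * np.ones((1, w))  # high in the north
    # broad, smooth relief: local slopes stay in the range a 30 m alpine
    # DTM actually shows rather than sawtooth micro-terrain
    relief = _smooth_field(rng, shape, sigma=10.0) * 0.04
    z = lo + (hi - lo) * np.clip(ramp + relief, 0.0, 1.0)

    boundary_noise = _smooth_field(rng, shape, sigma=5.0) * 120.0  # m of jitter
    zb = z + boundary_noise
    l1 = np.zeros(shape, dtype=np.uint16)
    l1[zb < 1500] = 4
    l1[(zb >= 1500) & (zb < 2200)] = 5
    l1[(zb >= 2200) & (zb < 2750)] = 6
    l1[(zb >= 2750) & (zb < 3300)] = 1
    l1[zb >= 3300] = 2

    # shrub patches interleaved with grassland above the treeline
    shrub_field = _smooth_field(rng, shape, sigma=4.0)
    l1[(l1 == 6) & (shrub_field > 0.55)] = 7

    # a lake in the valley bottom with a wetland fringe
    cy, cx = int(h * 0.88), int(w * 0.30)
    yy, xx = np.mgrid[0:h, 0:w]
    lake = (yy - cy) ** 2 + (xx - cx) ** 2 <= (min(h, w) * 0.06) ** 2
    fringe = ndimage.binary_dilation(lake, iterations=2) & ~lake
    l1[lake] = 3
    l1[fringe] = 8
    z[lake] = z[lake].min()

    # L2: partition each vegetated parent with a correlated field
    l2 = np.zeros(shape, dtype=np.uint16)
    part_field = _smooth_field(rng, shape, sigma=5.0)
    for parent in legend.vegetation_l1:
        children = legend.children_of(parent)[:3]  # three habitats per parent
        zone = l1 == parent
        if not zone.any():
            continue
        qs = np.quantile(part_field[zone], np.linspace(0, 1, len(children) + 1))
        qs[0], qs[-1] = -np.inf, np.inf
        for i, child in enumerate(children):
            l2[zone & (part_field >= qs[i]) & (part_field < qs[i + 1])] = child

    dtm = Grid(values=z, nodata=None)
    return dtm, l1, l2


def generate_world(
    seed: int,
    shape: tuple[int, int] = (128, 128),
    years: list[int] | None = None,
    l2_separation: float = 0.03,
    legend: Legend | None = None,
) -> SyntheticWorld:
    """A world whose true maps are initially identical across years."""
    legend = legend or default_legend()
    years = list(years) if years is not None else list(range(2000, 2010))
    dtm, l1, l2 = generate_landscape(seed, shape, legend=legend)
    return SyntheticWorld(
        seed=seed,
        dtm=dtm,
        years=years,
        true_l1={y: l1.copy() for y in years},
        true_l2={y: l2.copy() for y in years},
        legend=legend,
        l2_separation=l2_separation,
    )


def _grow_patch(
    rng: np.random.Generator, eligible: np.ndarray, size: int
) -> list[tuple[int, int]]:
    """Grow one 4-connected patch of ``size`` pixels inside ``eligible``."""
    seeds = np.argwhere(eligible)
    if len(seeds) == 0:
        return []
    start = tuple(seeds[rng.integers(len(seeds))])
    patch = {start}
    frontier = [start]
    while frontier and len(patch) < size:
        r, c = frontier.pop(rng.integers(len(frontier)))
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nb = (r + dr, c + dc)
            if (
                0 <= nb[0] < eligible.shape[0]
                and 0 <= nb[1] < eligible.shape[1]
                and eligible[nb]
                and nb not in patch
            ):
                patch.add(nb)
                frontier.append(nb)
                if len(patch) >= size:
                    break
    return sorted(patch)


def plant_changes(
    world: SyntheticWorld,
    specs: list[tuple[int, int, int, int, int]],
) -> SyntheticWorld:
    """Flip contiguous patches (year, from, to, n_patches, patch_size).

    Each patch changes class from the given year onwards; the ledger
    records every flipped pixel.  Later specs win on overlapping pixels
    and the ledger reflects the final state.
    """
    rng = _rng(world.seed, "changes")
    for year, from_class, to_class, n_patches, patch_size in specs:
        if year not in world.years:
            raise ValidationError(f"change year {year} outside the world's years")
        flipped: list[tuple[int, int]] = []
        for _ in range(n_patches):
            eligible = (world.true_l1[year] == from_class)
            for r, c in flipped:
                eligible[r, c] = False
            patch = _grow_patch(rng, eligible, patch_size)
            if len(patch) < patch_size:
                warnings.warn(
                    f"only {len(patch)}/{patch_size} pixels available for "
                    f"{from_class}->{to_class} in {year}"
                )
            flipped.extend(patch)
        for y in world.years:
            if y >= year:
                for r, c in flipped:
                    world.true_l1[y][r, c] = to_class
                    world.true_l2[y][r, c] = 0  # habitat identity resets with the class
        # overwrite any earlier ledger claim on these pixels
        pixel_set = set(flipped)
        for event in world.ledger:
            event.pixels = [p for p in event.pixels if p not in pixel_set]
        world.ledger.append(
            ChangeEvent(year=year, from_class=from_class, to_class=to_class, pixels=flipped)
        )
    world.ledger = [e for e in world.ledger if e.pixels]
    return world


def _signature(world: SyntheticWorld, l1: int, l2: int) -> np.ndarray:
    base = np.array(SPECTRA[l1])
    if l2 and l1 in world.legend.vegetation_l1:
        rank = world.legend.children_of(l1).index(l2)
        offset = np.zeros(6)
        offset[3] = (rank - 1) * world.l2_separation          # nir
        offset[4] = (1 - rank) * world.l2_separation * 0.8    # swir1
        base = base + offset
    return base


def _phenology_offset(l1: int, doy: int) -> np.ndarray:
    amp, peak = PHENOLOGY.get(l1, (0.0, 200))
    pulse = amp * np.exp(-((doy - peak) ** 2) / (2.0 * 30.0**2))
    offset = np.zeros(6)
    offset[3] = pulse
    offset[2] = -pulse / 4.0
    return offset


def _season_doys(season: str, n: int) -> list[int]:
    lo, hi = (166, 243) if season == "growing" else (258, 334)
    return [int(d) for d in np.linspace(lo + 5, hi - 5, n)]


def _snowline(season: str, doy: int) -> float:
    if season == "growing":
        return 2500.0 + 10.0 * (doy - 166)
    return 3500.0 - 8.0 * (doy - 258)


def render_scenes(
    world: SyntheticWorld,
    years: list[int] | None = None,
    scenes_per_season: int = 3,
    noise_sd: float = 0.01,
    cloud_frac: float = 0.10,
    snow_by_elevation: bool = True,
    solar_zenith: dict[str, float] | None = None,
    solar_azimuth: float = 180.0,
    diffuse_fraction: float = 0.25,
) -> list[SceneStack]:
    """Render per-season scene stacks for the requested years.

    Reflectance is the class signature plus phenology and Gaussian sensor
    noise, scaled by the slope illumination (cos i + d) / (cos theta_z + d)
    where ``d`` is a diffuse-skylight term — direct beam plus diffuse
    irradiance, so shaded slopes darken strongly but never to zero — making
    topographic correction exercisable.  Cloud and seasonal-snow blobs come
    with matching masks; snow probability rises with elevation and towards
    the season edges.  Perennial snow/ice pixels are scene content, not mask.
    """
    years = years or world.years
    solar_zenith = solar_zenith or {"growing": 35.0, "senescence": 55.0}
    terrain = terrain_from_dtm(world.dtm)
    z = world.dtm.values
    noise_rng = _rng(world.seed, "noise")
    cloud_rng = _rng(world.seed, "clouds")
    sensors = ("TM", "ETM+", "OLI")
    scenes: list[SceneStack] = []
    for year in years:
        l1 = world.true_l1[year]
        l2 = world.true_l2[year]
        combos = {
            (int(a), int(b)) for a, b in zip(l1.ravel().tolist(), l2.ravel().tolist())
        }
        for season in ("growing", "senescence"):
            tz = solar_zenith[season]
            cos_i = compute_illumination(terrain, tz, solar_azimuth).values
            illum = (np.clip(cos_i, 0.0, None) + diffuse_fraction) / (
                np.cos(np.deg2rad(tz)) + diffuse_fraction
            )
            for k, doy in enumerate(_season_doys(season, scenes_per_season)):
                base = np.zeros((6, *world.shape))
                for a, b in combos:
                    sig = _signature(world, a, b) + _phenology_offset(a, doy)
                    sel = (l1 == a) & (l2 == b)
                    base[:, sel] = sig[:, None]
                base *= illum[None]
                if noise_sd > 0:
                    base += noise_rng.normal(0.0, noise_sd, size=base.shape)
                base = np.clip(base, 0.0, 1.0)

                if cloud_frac >= 1.0:
                    cloud = np.ones(world.shape, dtype=bool)
                elif cloud_frac <= 0.0:
                    cloud = np.zeros(world.shape, dtype=bool)
                else:
                    cf = _smooth_field(cloud_rng, world.shape, sigma=6.0)
                    cloud = cf > np.quantile(cf, 1.0 - cloud_frac)
                shadow = np.roll(cloud, (4, 4), axis=(0, 1)) & ~cloud
                if cloud_frac >= 1.0:
                    shadow = np.zeros(world.shape, dtype=bool)

                if snow_by_elevation:
                    jitter = _smooth_field(cloud_rng, world.shape, sigma=5.0) * 150.0
                    snow = (z + jitter > _snowline(season, doy)) & (l1 != 2)
                else:
                    snow = np.zeros(world.shape, dtype=bool)
                # snow on the ground looks like snow, whatever lies beneath
                snow_vis = snow & ~cloud
                base[:, snow_vis] = np.array(SPECTRA[2])[:, None]

                date = _dt.date(year, 1, 1) + _dt.timedelta(days=doy - 1)
                bands = {
                    name: world.dtm.like(base[i], nodata=None)
                    for i, name in enumerate(BAND_NAMES)
                }
                scenes.append(
                    SceneStack(
                        bands=bands,
                        cloud_mask=cloud,
                        shadow_mask=shadow,
                        snow_mask=snow,
                        sensor_id=sensors[k % len(sensors)],
                        date=date,
                        solar_zenith=tz,
                        solar_azimuth=solar_azimuth,
                        scene_cloud_pct=100.0 * cloud.mean(),
                        scene_snowfree_pct=100.0 * (1.0 - snow.mean()),
                    )
                )
    return scenes
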