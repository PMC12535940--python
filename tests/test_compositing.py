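"""Terrain correction, scene filtering, BAP scoring and compositing."""

import datetime as dt

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from retrohab.compositing import (
    BapCriteria,
    SceneStack,
    TerrainModel,
    compose_bap,
    compute_illumination,
    filter_scenes,
    improved_cosine_correct,
    score_observation,
    spectral_index,
)
from retrohab.core import Grid, ValidationError


def _terrain(slope_deg, aspect_deg, shape=(4, 4)):
    z = Grid(np.zeros(shape))
    return TerrainModel(
        elevation=z,
        slope=z.like(np.full(shape, np.deg2rad(slope_deg))),
        aspect=z.like(np.full(shape, np.deg2rad(aspect_deg))),
    )


class TestIllumination:
    def test_flat_terrain_equals_cos_solar_zenith(self):
        ci = compute_illumination(_terrain(0, 0), 30.0, 120.0)
        assert ci.values == pytest.approx(np.cos(np.deg2rad(30)), abs=1e-12)

    def test_sun_facing_slope_is_fully_illuminated(self):
        ci = compute_illumination(_terrain(30, 120), 30.0, 120.0)
        assert ci.values == pytest.approx(1.0, abs=1e-12)

    def test_opposed_45deg_slope_is_grazing(self):
        ci = compute_illumination(_terrain(45, 300), 45.0, 120.0)
        assert ci.values == pytest.approx(0.0, abs=1e-12)

    def test_zenith_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            compute_illumination(_terrain(0, 0), 95.0, 120.0)


class TestImprovedCosine:
    def test_pixel_at_mean_illumination_unchanged(self):
        band = Grid(np.array([[0.2, 0.4]]))
        cos_i = band.like(np.array([[0.6, 0.6]]))
        out = improved_cosine_correct(band, cos_i)
        assert out.values == pytest.approx(band.values)

    def test_hand_computed_correction(self):
        # pixel cos_i 0.3 against scene mean 0.6 brightens 0.2 to 0.3
        band = Grid(np.array([[0.2, 0.2]]))
        cos_i = band.like(np.array([[0.3, 0.9]]))  # mean 0.6
        out = improved_cosine_correct(band, cos_i)
        assert out.values[0, 0] == pytest.approx(0.3)

    def test_flat_scene_identity(self):
        band = Grid(np.random.default_rng(0).random((5, 5)))
        cos_i = band.like(np.full((5, 5), 0.83))
        out = improved_cosine_correct(band, cos_i)
        assert np.allclose(out.values, band.values)

    def test_mean_reflectance_preserved_for_symmetric_illumination(self):
        # cos_i symmetric about its mean, uniform reflectance: first-order
        # mean preservation is exact
        band = Grid(np.full((2, 2), 0.31))
        cos_i = band.like(np.array([[0.5, 0.7], [0.6, 0.6]]))
        out = improved_cosine_correct(band, cos_i)
        assert out.values.mean() == pytest.approx(band.values.mean(), abs=1e-6)

    def test_nonpositive_mean_illumination_fails(self):
        band = Grid(np.full((2, 2), 0.2))
        cos_i = band.like(np.full((2, 2), -0.1))
        with pytest.raises(ArithmeticError):
            improved_cosine_correct(band, cos_i)


def _scene(shape=(8, 8), date=dt.date(2000, 7, 15), cloud=None, shadow=None,
           snow=None, value=0.3, sensor="OLI", cloud_pct=0.0, snowfree=100.0,
           opacity=None, nir=None, red=None):
    mk = lambda v: Grid(np.full(shape, float(v)))
    bands = {
        "blue": mk(value), "green": mk(value), "red": mk(red if red is not None else value),
        "nir": mk(nir if nir is not None else value), "swir1": mk(value), "swir2": mk(value),
    }
    z = np.zeros(shape, dtype=bool)
    return SceneStack(
        bands=bands,
        cloud_mask=cloud if cloud is not None else z.copy(),
        shadow_mask=shadow if shadow is not None else z.copy(),
        snow_mask=snow if snow is not None else z.copy(),
        sensor_id=sensor,
        date=date,
        solar_zenith=35.0,
        solar_azimuth=180.0,
        scene_cloud_pct=cloud_pct,
        scene_snowfree_pct=snowfree,
        opacity=opacity,
    )


class TestFilterScenes:
    def test_above_threshold_discarded(self):
        assert filter_scenes([_scene(cloud_pct=75.0)]) == []

    def test_exactly_at_threshold_retained(self):
        s = _scene(cloud_pct=70.0)
        assert filter_scenes([s]) == [s]

    def test_empty_input(self):
        assert filter_scenes([]) == []

    def test_order_preserved(self):
        a, b, c = _scene(cloud_pct=10), _scene(cloud_pct=80), _scene(cloud_pct=20)
        assert filter_scenes([a, b, c]) == [a, c]


class TestScoreObservation:
    def test_all_criteria_maximal_scores_one(self):
        crit = BapCriteria()
        on_target = dt.date(2001, 1, 1) + dt.timedelta(days=crit.target_doy["growing"] - 1)
        s = _scene(date=on_target)
        score = score_observation(s, (0, 0), crit, dist_to_cloud=np.inf,
                                  dist_to_snow=np.inf, season="growing")
        assert score == pytest.approx(1.0)

    def test_farther_from_cloud_scores_strictly_higher(self):
        crit = BapCriteria()
        s = _scene()
        near = score_observation(s, (0, 0), crit, 2.0, np.inf)
        far = score_observation(s, (0, 0), crit, 50.0, np.inf)
        assert far > near

    def test_masked_pixel_is_ineligible_not_zero(self):
        snow = np.zeros((8, 8), dtype=bool)
        snow[0, 0] = True
        s = _scene(snow=snow)
        assert score_observation(s, (0, 0), BapCriteria(), np.inf, np.inf) is None
        assert score_observation(s, (1, 1), BapCriteria(), np.inf, np.inf) is not None

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            BapCriteria(weights={"sensor": 0.5, "doy": 0.2, "dist_cloud": 0.1,
                                 "dist_snow": 0.1, "scene_snowfree": 0.05, "opacity": 0.0})

    @pytest.mark.parametrize("raw_input", ["dist_cloud", "dist_snow", "snowfree", "doy"])
    def test_monotone_in_each_criterion(self, raw_input):
        crit = BapCriteria()
        target = crit.target_doy["growing"]
        prev = -np.inf
        for step in range(6):
            kw = dict(date=dt.date(2000, 7, 1), snowfree=100.0)
            d_cloud = d_snow = np.inf
            if raw_input == "dist_cloud":
                d_cloud = 2.0 + 5 * step
            elif raw_input == "dist_snow":
                d_snow = 2.0 + 5 * step
            elif raw_input == "snowfree":
                kw["snowfree"] = 40.0 + 10 * step
            elif raw_input == "doy":
                # move the acquisition closer to the target day
                kw["date"] = dt.date(2000, 1, 1) + dt.timedelta(days=target - 40 + 6 * step)
            score = score_observation(_scene(**kw), (0, 0), crit, d_cloud, d_snow)
            assert score >= prev
            prev = score


def _brute_force_bap(scenes, year, season, criteria):
    """Independent per-(scene, pixel) argmax with explicit distance scans."""
    cands = [s for s in scenes
             if s.date.year == year and criteria.in_window(s.date, season)
             and s.scene_cloud_pct <= criteria.cloud_threshold]
    shape = cands[0].cloud_mask.shape
    coords = np.argwhere(np.ones(shape, dtype=bool))
    winner = np.full(shape, -1)
    target = criteria.target_doy[season]
    for r, c in coords:
        best = None
        for idx, s in enumerate(cands):
            occl = s.cloud_mask | s.shadow_mask
            d_cloud = (cdist([[r, c]], np.argwhere(occl)).min()
                       if occl.any() else np.inf)
            d_snow = (cdist([[r, c]], np.argwhere(s.snow_mask)).min()
                      if s.snow_mask.any() else np.inf)
            score = score_observation(s, (r, c), criteria, d_cloud, d_snow, season)
            if score is None:
                continue
            key = (score, -abs(s.doy - target), s.date.toordinal())
            if best is None or key > best[0]:
                best = (key, idx)
        if best is not None:
            winner[r, c] = best[1]
    return winner


class TestComposeBap:
    def test_single_cloudfree_scene_wins_everywhere(self):
        s = _scene(date=dt.date(2000, 7, 10), value=0.37)
        comp = compose_bap([s], 2000, "growing")
        assert (comp.provenance.values == 0).all()
        assert np.allclose(comp.bands["nir"].values, 0.37)

    def test_complementary_masks_split_provenance(self):
        shape = (6, 6)
        left = np.zeros(shape, dtype=bool)
        left[:, :3] = True
        a = _scene(shape, date=dt.date(2000, 7, 10), cloud=left.copy(), value=0.2)
        b = _scene(shape, date=dt.date(2000, 7, 20), cloud=~left, value=0.8)
        comp = compose_bap([a, b], 2000, "growing")
        prov = comp.provenance.values
        assert (prov >= 0).all()
        assert (prov[:, :3] == 1).all() and (prov[:, 3:] == 0).all()
        assert np.allclose(comp.bands["red"].values[:, :3], 0.8)

    def test_fully_occluded_pixel_is_nodata(self):
        cloud = np.ones((4, 4), dtype=bool)
        scenes = [_scene((4, 4), cloud=cloud.copy(), cloud_pct=50.0) for _ in range(3)]
        comp = compose_bap(scenes, 2000, "growing")
        assert (comp.provenance.values == -1).all()
        assert np.isnan(comp.bands["nir"].values).all()

    def test_matches_brute_force_argmax_on_random_stacks(self, rng):
        crit = BapCriteria()
        shape = (12, 12)
        scenes = []
        for k in range(5):
            cloud = rng.random(shape) < 0.25
            snow = rng.random(shape) < 0.15
            scenes.append(
                _scene(shape, date=dt.date(2000, 6, 20) + dt.timedelta(days=12 * k),
                       cloud=cloud, snow=snow, value=float(rng.random()),
                       snowfree=100 * (1 - snow.mean()), cloud_pct=100 * cloud.mean())
            )
        comp = compose_bap(scenes, 2000, "growing", crit)
        oracle = _brute_force_bap(scenes, 2000, "growing", crit)
        assert np.array_equal(comp.provenance.values, oracle)

    def test_no_masked_observation_ever_selected(self, rng):
        shape = (10, 10)
        scenes = []
        for k in range(4):
            cloud = rng.random(shape) < 0.4
            shadow = rng.random(shape) < 0.2
            snow = rng.random(shape) < 0.2
            scenes.append(_scene(shape, date=dt.date(2000, 7, 1 + 7 * k),
                                 cloud=cloud, shadow=shadow, snow=snow))
        comp = compose_bap(scenes, 2000, "growing")
        prov = comp.provenance.values
        for r, c in np.argwhere(prov >= 0):
            s = scenes[prov[r, c]]
            assert not (s.cloud_mask[r, c] or s.shadow_mask[r, c] or s.snow_mask[r, c])

    def test_empty_window_warns_not_fails(self):
        with pytest.warns(UserWarning):
            comp = compose_bap([_scene(date=dt.date(2000, 1, 5))], 2000, "growing")
        assert comp.bands == {}


class TestSpectralIndex:
    def _comp(self, nir, red):
        s = _scene(date=dt.date(2000, 7, 10), nir=nir, red=red)
        return compose_bap([s], 2000, "growing")

    def test_equal_bands_give_zero(self):
        assert spectral_index(self._comp(0.3, 0.3), "ndvi").values == pytest.approx(0.0)

    def test_hand_computed_ndvi(self):
        out = spectral_index(self._comp(0.5, 0.1), "ndvi")
        assert out.values == pytest.approx(2 / 3, abs=1e-4)

    def test_zero_denominator_is_nodata(self):
        out = spectral_index(self._comp(0.0, 0.0), "ndvi")
        assert np.isnan(out.values).all()

    def test_unknown_index_rejected(self):
        with pytest.raises(ValidationError):
            spectral_index(self._comp(0.5, 0.1), "bogus")
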