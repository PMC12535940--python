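"""Accuracy metrics against brute-force definitions; patch structure metrics."""

import numpy as np
import pandas as pd
import pytest

from retrohab.core import Grid, ValidationError
from retrohab.validate import (
    ConfusionMatrix,
    accuracy_structure_correlation,
    class_metrics,
    confusion,
    overall_metrics,
    patch_metrics,
)


def brute_force_metrics(counts, classes):
    """All metrics from first principles: rows predicted, columns reference."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    k = len(classes)
    out = {"oa": np.trace(counts) / n}
    per = {}
    recalls, specs = [], []
    for i in range(k):
        tp = counts[i, i]
        col = counts[:, i].sum()
        row = counts[i, :].sum()
        fp = row - tp
        fn = col - tp
        tn = n - tp - fp - fn
        pa = tp / col if col > 0 else np.nan
        ua = tp / row if row > 0 else np.nan
        f1 = 2 * pa * ua / (pa + ua) if (pa + ua) > 0 else np.nan
        spec = tn / (tn + fp) if (tn + fp) > 0 else np.nan
        tss = pa + spec - 1
        per[classes[i]] = {"pa": pa, "ua": ua, "f1": f1, "tss": tss}
        recalls.append(pa)
        specs.append(spec)
    out["ba"] = np.nanmean([(r + s) / 2 for r, s in zip(recalls, specs)])
    pe = sum(counts[i, :].sum() * counts[:, i].sum() for i in range(k)) / n**2
    out["kappa"] = (out["oa"] - pe) / (1 - pe) if pe < 1 else np.nan
    # inverse-prevalence weighted recall
    w = np.array([n / counts[:, i].sum() if counts[:, i].sum() > 0 else 0 for i in range(k)])
    if w.sum() > 0:
        w = w / w.sum()
        out["wa"] = float(np.nansum(w * np.nan_to_num(recalls)))
    return out, per


class TestConfusion:
    def test_perfect_map_is_diagonal(self, rng):
        vals = rng.integers(1, 4, size=(6, 6)).astype(np.uint16)
        cm = confusion(Grid(vals, nodata=0), Grid(vals, nodata=0))
        assert np.trace(cm.counts) == cm.n

    def test_disjoint_labels_all_off_diagonal(self):
        pred = np.full((3, 3), 1, dtype=np.uint16)
        ref = np.full((3, 3), 2, dtype=np.uint16)
        cm = confusion(Grid(pred, nodata=0), Grid(ref, nodata=0))
        assert np.trace(cm.counts) == 0

    def test_hand_built_tally(self):
        pred = np.array([[1, 1, 2], [2, 3, 3]], dtype=np.uint16)
        ref = np.array([[1, 2, 2], [2, 3, 1]], dtype=np.uint16)
        cm = confusion(Grid(pred, nodata=0), Grid(ref, nodata=0))
        frame = cm.to_frame()
        assert frame.loc[1, 1] == 1 and frame.loc[1, 2] == 1
        assert frame.loc[2, 2] == 2 and frame.loc[3, 3] == 1 and frame.loc[3, 1] == 1

    def test_nodata_excluded_both_sides(self):
        pred = np.array([[1, 0], [1, 1]], dtype=np.uint16)
        ref = np.array([[1, 1], [0, 1]], dtype=np.uint16)
        cm = confusion(Grid(pred, nodata=0), Grid(ref, nodata=0))
        assert cm.n == 2

    def test_no_joint_samples_rejected(self):
        pred = np.array([[1, 0]], dtype=np.uint16)
        ref = np.array([[0, 1]], dtype=np.uint16)
        with pytest.raises(ValidationError):
            confusion(Grid(pred, nodata=0), Grid(ref, nodata=0))


class TestOverallMetrics:
    def test_hand_computed_two_class_fixture(self):
        cm = ConfusionMatrix(np.array([[40, 10], [5, 45]]), [1, 2])
        m = overall_metrics(cm)
        assert m["oa"] == pytest.approx(0.85)
        assert m["kappa"] == pytest.approx(0.70)

    def test_perfection(self):
        cm = ConfusionMatrix(np.diag([10, 20, 30]), [1, 2, 3])
        m = overall_metrics(cm)
        assert m["oa"] == m["ba"] == m["kappa"] == m["wa"] == 1.0

    def test_random_predictions_drive_kappa_to_zero(self, rng):
        p = rng.integers(1, 3, size=20000)
        r = rng.integers(1, 3, size=20000)
        cm = confusion(p.astype(np.uint16), r.astype(np.uint16))
        assert overall_metrics(cm)["kappa"] == pytest.approx(0.0, abs=0.03)

    def test_single_class_kappa_undefined(self):
        cm = ConfusionMatrix(np.array([[7.0]]), [1])
        assert np.isnan(overall_metrics(cm)["kappa"])


class TestClassMetrics:
    def test_hand_computed_fixture(self):
        cm = ConfusionMatrix(np.array([[40, 10], [5, 45]]), [1, 2])
        t = class_metrics(cm)
        assert t.loc[1, "pa"] == pytest.approx(40 / 45)
        assert t.loc[1, "ua"] == pytest.approx(0.80)
        assert t.loc[1, "f1"] == pytest.approx(0.8421, abs=1e-4)
        assert t.loc[1, "tss"] == pytest.approx(0.7071, abs=1e-4)

    def test_never_seen_class_all_undefined(self):
        cm = ConfusionMatrix(np.array([[5, 0, 0], [0, 5, 0], [0, 0, 0]]), [1, 2, 3])
        t = class_metrics(cm)
        assert t.loc[3].isna().all()

    def test_agrees_with_brute_force_on_random_matrices(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 7))
            counts = rng.integers(0, 30, size=(k, k)).astype(float)
            if counts.sum() == 0:
                continue
            classes = list(range(1, k + 1))
            cm = ConfusionMatrix(counts, classes)
            expected_overall, expected_per = brute_force_metrics(counts, classes)
            got_overall = overall_metrics(cm)
            for key in ("oa", "ba", "kappa", "wa"):
                np.testing.assert_allclose(
                    got_overall[key], expected_overall.get(key, np.nan),
                    atol=1e-12, equal_nan=True,
                )
            got_per = class_metrics(cm)
            for c in classes:
                for key in ("pa", "ua", "f1", "tss"):
                    np.testing.assert_allclose(
                        got_per.loc[c, key], expected_per[c][key],
                        atol=1e-12, equal_nan=True,
                    )

    def test_binary_ba_tss_identity(self, rng):
        # for 2 classes, BA - 0.5 = mean TSS / 2
        for _ in range(50):
            counts = rng.integers(1, 40, size=(2, 2)).astype(float)
            cm = ConfusionMatrix(counts, [1, 2])
            ba = overall_metrics(cm)["ba"]
            tss = class_metrics(cm)["tss"].mean()
            assert ba - 0.5 == pytest.approx(tss / 2, abs=1e-12)

    def test_metric_ranges(self, rng):
        for _ in range(100):
            counts = rng.integers(0, 20, size=(3, 3)).astype(float) + np.eye(3)
            cm = ConfusionMatrix(counts, [1, 2, 3])
            m = overall_metrics(cm)
            assert 0 <= m["oa"] <= 1 and 0 <= m["ba"] <= 1 and 0 <= m["wa"] <= 1
            assert -1 <= m["kappa"] <= 1
            t = class_metrics(cm)
            assert ((t[["pa", "ua", "f1"]] >= 0) | t[["pa", "ua", "f1"]].isna()).all().all()
            assert ((t["tss"] >= -1) & (t["tss"] <= 1) | t["tss"].isna()).all()


def flood_fill_patches(mask):
    """Oracle: 8-connected components by explicit flood fill."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    patches = []
    for r, c in np.argwhere(mask):
        if seen[r, c]:
            continue
        stack, patch = [(r, c)], []
        seen[r, c] = True
        while stack:
            y, x = stack.pop()
            patch.append((y, x))
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = y + dy, x + dx
                    if (0 <= ny < mask.shape[0] and 0 <= nx < mask.shape[1]
                            and mask[ny, nx] and not seen[ny, nx]):
                        seen[ny, nx] = True
                        stack.append((ny, nx))
        patches.append(patch)
    return patches


class TestPatchMetrics:
    def test_2x2_patch(self):
        vals = np.zeros((6, 6), dtype=np.uint16)
        vals[2:4, 2:4] = 1
        stats = patch_metrics(Grid(vals, nodata=0)).table
        assert stats.loc[1, "n_patches"] == 1
        assert stats.loc[1, "mean_patch_area_ha"] == pytest.approx(0.36)
        assert stats.loc[1, "total_edge_m"] == pytest.approx(240.0)
        assert stats.loc[1, "mean_shape_index"] == pytest.approx(1.1284, abs=1e-4)

    def test_two_patches_mean_area(self):
        vals = np.zeros((10, 10), dtype=np.uint16)
        vals[0:2, 0:2] = 1  # 4 px
        vals[6:8, 4:7] = 1  # 6 px
        stats = patch_metrics(Grid(vals, nodata=0)).table
        assert stats.loc[1, "n_patches"] == 2
        assert stats.loc[1, "mean_patch_area_ha"] == pytest.approx(0.45)

    def test_single_pixel_shape_index(self):
        vals = np.zeros((3, 3), dtype=np.uint16)
        vals[1, 1] = 1
        stats = patch_metrics(Grid(vals, nodata=0)).table
        assert stats.loc[1, "mean_shape_index"] == pytest.approx(
            120 / (2 * np.sqrt(np.pi * 900)), abs=1e-6
        )

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(10):
            vals = (rng.random((15, 15)) < 0.4).astype(np.uint16)
            stats = patch_metrics(Grid(vals, nodata=0), classes=[1]).table
            oracle = flood_fill_patches(vals == 1)
            if not oracle:
                assert stats.loc[1, "n_patches"] == 0
                continue
            assert stats.loc[1, "n_patches"] == len(oracle)
            mean_area = np.mean([len(p) for p in oracle]) * 0.09
            assert stats.loc[1, "mean_patch_area_ha"] == pytest.approx(mean_area)


class TestAccuracyStructureCorrelation:
    def _tables(self, acc, area):
        idx = pd.Index(range(1, len(acc) + 1), name="class")
        return (
            pd.DataFrame({"pa": acc}, index=idx),
            pd.DataFrame({"mean_patch_area_ha": area}, index=idx),
        )

    def test_perfect_linear_relation(self):
        m, p = self._tables([0.1, 0.2, 0.4, 0.8], [1.0, 2.0, 4.0, 8.0])
        r = accuracy_structure_correlation(m, p)
        assert r.loc["pa", "mean_patch_area_ha"] == pytest.approx(1.0)

    def test_anticorrelated(self):
        m, p = self._tables([0.9, 0.5, 0.1], [1.0, 5.0, 9.0])
        r = accuracy_structure_correlation(m, p)
        assert r.loc["pa", "mean_patch_area_ha"] == pytest.approx(-1.0)

    def test_independent_near_zero(self, rng):
        m, p = self._tables(rng.random(200).tolist(), rng.random(200).tolist())
        r = accuracy_structure_correlation(m, p)
        assert abs(r.loc["pa", "mean_patch_area_ha"]) < 0.2

    def test_undefined_below_three_pairs(self):
        m, p = self._tables([0.5, np.nan, 0.7], [1.0, 2.0, np.nan])
        r = accuracy_structure_correlation(m, p)
        assert np.isnan(r.loc["pa", "mean_patch_area_ha"])
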