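"""Retrospective training extraction from a single reference land-cover map.

A dated reference cartography (year ``T1``) is cleaned to the sensor's
minimum mapping unit, per-class signatures (mean/sd per predictor) are
computed over the reference pixels, and for every target year ``T2`` the
pixels whose predictor vector lies near the centre of their class's
standardised-distance (Z) distribution are retained as "pure", unchanged
training samples.  Pixels in the distribution tails — likely mixed or
changed since ``T1`` — are excluded, which yields annual training sets
without any multi-temporal ground truth.

Z for a pixel x in class c is the root-sum of per-predictor standardised
squared deviations, sqrt(sum_b ((x_b - mu_cb) / sigma_cb)^2); predictors are
standardised independently (no covariance term).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape

from .core import Grid, Legend, ValidationError

__all__ = [
    "ReferenceMap",
    "ClassSignature",
    "clean_cartography",
    "rasterize_polygons",
    "class_signature",
    "z_statistic",
    "select_pure_pixels",
    "build_annual_training",
]


@dataclass
class ReferenceMap:
    """Reference cartography: an L1 class grid, optional L2 grid, and its year."""

    l1: Grid
    reference_year: int
    l2: Grid | None = None
    legend: Legend | None = None

    def __post_init__(self) -> None:
        if self.legend is not None:
            codes = set(np.unique(self.l1.values)) - {0, self.l1.nodata}
            bad = codes - set(self.legend.l1_codes)
            if bad:
                raise ValidationError(f"unknown L1 codes in reference map: {sorted(bad)}")


@dataclass
class ClassSignature:
    """Per-class, per-predictor mean/sd/count from the reference epoch."""

    predictors: list[str]
    mean: dict[int, np.ndarray]
    sd: dict[int, np.ndarray]
    n: dict[int, int]
    degenerate: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def classes(self) -> list[int]:
        return sorted(self.mean)

    def usable(self, c: int) -> bool:
        return self.n.get(c, 0) >= 2


def _min_width_ok(geom, min_width_m: float) -> bool:
    """A patch passes if it survives erosion by just under half the min width.

    The erosion radius is shaved by 0.1% so a patch of exactly the minimum
    width is retained (the removal rule is strict "<").
    """
    eroded = geom.buffer(-(min_width_m / 2.0) * (1.0 - 1e-3))
    return not eroded.is_empty


def clean_cartography(
    features: list[dict],
    template: Grid,
    mmu_m2: float = 900.0,
    min_width_m: float = 30.0,
    reference_year: int = 2009,
    legend: Legend | None = None,
    l1_property: str = "l1",
    l2_property: str = "l2",
) -> ReferenceMap:
    """Clean polygon cartography and rasterize it to the common lattice.

    ``features`` are GeoJSON-style Feature dicts.  Patches with area
    strictly below ``mmu_m2`` or with any dimension strictly below
    ``min_width_m`` are removed; the remainder is rasterized by the
    cell-centre rule (a cell takes the polygon containing its centre).
    """
    kept: list[tuple[object, int, int]] = []
    for i, feat in enumerate(features):
        try:
            geom = shapely_shape(feat["geometry"])
        except Exception as exc:  # pragma: no cover - malformed input path
            raise ValidationError(f"feature {i}: unreadable geometry ({exc})") from exc
        if not geom.is_valid:
            raise ValidationError(f"feature {i}: invalid geometry")
        if geom.area < mmu_m2:
            continue
        if not _min_width_ok(geom, min_width_m):
            continue
        props = feat.get("properties", {})
        l1 = int(props[l1_property])
        l2 = int(props.get(l2_property, 0) or 0)
        kept.append((geom, l1, l2))

    l1_grid = rasterize_polygons([(g, c) for g, c, _ in kept], template)
    l2_grid = rasterize_polygons([(g, c) for g, _, c in kept], template)
    return ReferenceMap(
        l1=l1_grid, l2=l2_grid, reference_year=reference_year, legend=legend
    )


def rasterize_polygons(shapes: list[tuple[object, int]], template: Grid) -> Grid:
    """Burn (geometry, code) pairs onto the template lattice by cell centres."""
    h, w = template.shape
    t = template.transform
    out = np.zeros((h, w), dtype=np.uint16)
    cols = np.arange(w) + 0.5
    rows = np.arange(h) + 0.5
    xs = t.a * cols + t.c
    ys = t.e * rows + t.f
    xx, yy = np.meshgrid(xs, ys)
    for geom, code in shapes:
        if code == 0:
            continue
        minx, miny, maxx, maxy = geom.bounds
        sel = (xx >= minx) & (xx <= maxx) & (yy >= miny) & (yy <= maxy)
        if not sel.any():
            continue
        r, c = np.nonzero(sel)
        inside = shapely.contains_xy(geom, xx[r, c], yy[r, c])
        out[r[inside], c[inside]] = code
    return template.like(out, nodata=0)


def _predictor_stack(predictors: dict[str, Grid]) -> tuple[list[str], np.ndarray, np.ndarray]:
    names = list(predictors)
    stack = np.stack([np.asarray(predictors[n].values, dtype=float) for n in names])
    valid = np.ones(stack.shape[1:], dtype=bool)
    for n in names:
        valid &= predictors[n].valid_mask()
    return names, stack, valid


def class_signature(
    reference: ReferenceMap, predictors: dict[str, Grid], level: str = "L1"
) -> ClassSignature:
    """Per-class mean and sample standard deviation of every predictor.

    Classes with fewer than two valid pixels are flagged unusable rather
    than failing; predictors that are constant within a class are flagged
    degenerate and later dropped from that class's Z.
    """
    ref_grid = reference.l1 if level == "L1" else reference.l2
    if ref_grid is None:
        raise ValidationError(f"reference map has no {level} layer")
    names, stack, valid = _predictor_stack(predictors)
    labels = np.asarray(ref_grid.values)
    mean: dict[int, np.ndarray] = {}
    sd: dict[int, np.ndarray] = {}
    n: dict[int, int] = {}
    degenerate: dict[int, np.ndarray] = {}
    for c in sorted(set(np.unique(labels)) - {0}):
        sel = (labels == c) & valid
        count = int(sel.sum())
        n[c] = count
        if count == 0:
            warnings.warn(f"class {c}: no valid reference pixels")
            continue
        vals = stack[:, sel]
        mean[c] = vals.mean(axis=1)
        sd[c] = vals.std(axis=1, ddof=1) if count >= 2 else np.zeros(len(names))
        # constant-within-class predictors (up to float round-off) are
        # degenerate and must not enter this class's Z
        degenerate[c] = sd[c] <= 1e-9 * np.maximum(1.0, np.abs(mean[c]))
        sd[c] = np.where(degenerate[c], 0.0, sd[c])
    return ClassSignature(predictors=names, mean=mean, sd=sd, n=n, degenerate=degenerate)


def z_statistic(x: np.ndarray, c: int, sig: ClassSignature) -> float:
    """Standardised distance of one predictor vector from its class signature."""
    if c not in sig.mean:
        raise ValidationError(f"class {c} has no signature")
    keep = ~sig.degenerate[c]
    if not keep.any():
        raise ValidationError(f"class {c}: all predictors degenerate")
    x = np.asarray(x, dtype=float)[keep]
    z = (x - sig.mean[c][keep]) / sig.sd[c][keep]
    return float(np.sqrt(np.sum(z**2)))


def _z_grid(stack: np.ndarray, sel: np.ndarray, c: int, sig: ClassSignature) -> np.ndarray:
    keep = ~sig.degenerate[c]
    if not keep.any():
        # all predictors constant in this class: every member is at the centre
        return np.zeros(int(sel.sum()))
    vals = stack[keep][:, sel]
    z = (vals - sig.mean[c][keep, None]) / sig.sd[c][keep, None]
    return np.sqrt(np.sum(z**2, axis=0))


def select_pure_pixels(
    reference: ReferenceMap,
    predictors: dict[str, Grid],
    sig: ClassSignature,
    year: int,
    retention_q: float = 0.5,
    level: str = "L1",
) -> pd.DataFrame:
    """Keep, per class, the pixels inside the central ``retention_q`` of Z.

    Returns a training table with columns ``row, col, year, label, z`` plus
    one column per predictor.  Classes without a usable signature, or whose
    pixels are all invalid that year, are absent with a warning.
    """
    ref_grid = reference.l1 if level == "L1" else reference.l2
    names, stack, valid = _predictor_stack(predictors)
    if names != sig.predictors:
        raise ValidationError("predictor set does not match the signature")
    labels = np.asarray(ref_grid.values)
    frames: list[pd.DataFrame] = []
    for c in sorted(set(np.unique(labels)) - {0}):
        if not sig.usable(c):
            warnings.warn(f"class {c}: signature unusable (n < 2); skipped")
            continue
        sel = (labels == c) & valid
        if not sel.any():
            warnings.warn(f"class {c}: no valid pixels in year {year}")
            continue
        z = _z_grid(stack, sel, c, sig)
        cutoff = float(np.quantile(z, retention_q))
        keep = z <= cutoff
        rows, cols = np.nonzero(sel)
        frame = pd.DataFrame(
            {
                "row": rows[keep],
                "col": cols[keep],
                "year": year,
                "label": c,
                "z": z[keep],
            }
        )
        for i, name in enumerate(names):
            frame[name] = stack[i][sel][keep]
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=["row", "col", "year", "label", "z", *names])
    return pd.concat(frames, ignore_index=True)


def build_annual_training(
    reference: ReferenceMap,
    predictor_stacks: dict[int, dict[str, Grid]],
    retention_q: float = 0.5,
    level: str = "L1",
) -> dict[int, pd.DataFrame]:
    """One pure-pixel training table per year.

    Signatures are computed once from the reference-year stack (``T1``) and
    every year is screened against them, so pixels that changed after
    (or before) the reference epoch fall in the tails and are excluded.
    """
    t1 = reference.reference_year
    if t1 not in predictor_stacks:
        raise ValidationError(f"reference year {t1} missing from predictor stacks")
    sig = class_signature(reference, predictor_stacks[t1], level=level)
    tables: dict[int, pd.DataFrame] = {}
    for year in sorted(predictor_stacks):
        stack = predictor_stacks[year]
        # only predictors present every year can be screened against T1
        common = {n: g for n, g in stack.items() if n in sig.predictors}
        if list(common) != sig.predictors:
            sub_sig = class_signature(
                reference, {n: predictor_stacks[t1][n] for n in common}, level=level
            )
        else:
            sub_sig = sig
        try:
            tables[year] = select_pure_pixels(
                reference, common, sub_sig, year, retention_q=retention_q, level=level
            )
        except ValidationError as exc:
            warnings.warn(f"year {year} skipped: {exc}")
    return tables
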