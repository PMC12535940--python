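"""Temporal filtering, decadal aggregation, trajectory typing and change rates.

Three cleaning rules run in a fixed order over each pixel's label
trajectory: (i) gaps are filled with the modal class of a +/-3-year
window; (ii) pixels that are water for more than half the series become
water throughout (persistent water bodies); (iii) classes appearing in
exactly one year are absorbed into the trajectory's dominant class.
Cleaned series are aggregated to roughly decadal windows by per-window
mode, trajectories are typed stable / transition / mixed, and change is
summarised as class-to-class transition matrices (in hectares and percent
of changed area) and as least-squares area-change rates (ha per year),
optionally stratified by region and altitudinal belt.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .core import ClassMapSeries, Grid, ValidationError, extract_trajectories, series_from_trajectories

__all__ = [
    "AggregationScheme",
    "ElevationBands",
    "TransitionMatrix",
    "fill_gaps",
    "enforce_water_persistence",
    "remove_singletons",
    "apply_rules",
    "apply_rules_series",
    "decadal_aggregate",
    "classify_trajectory",
    "trajectory_type_map",
    "transition_matrix",
    "change_rate",
    "trend",
    "elevation_stratify",
]

MISSING = 0
WATER_CODE = 3


@dataclass(frozen=True)
class AggregationScheme:
    """Ordered aggregation windows; half-open [start, end) except the last,
    which is closed so the final year belongs to the final window."""

    windows: tuple[tuple[int, int], ...] = (
        (1985, 1995),
        (1995, 2005),
        (2005, 2015),
        (2015, 2023),
    )

    def __post_init__(self) -> None:
        for (a0, a1), (b0, b1) in zip(self.windows, self.windows[1:]):
            if b0 < a1:
                raise ValidationError("aggregation windows must be ordered")

    def years_in(self, window: tuple[int, int], years: list[int]) -> list[int]:
        start, end = window
        last = window == self.windows[-1]
        return [y for y in years if start <= y < end or (last and y == end)]

    @classmethod
    def evenly(cls, years: list[int], n_windows: int) -> "AggregationScheme":
        """Split a year list into ``n_windows`` near-equal consecutive windows."""
        chunks = np.array_split(np.asarray(years), n_windows)
        windows = []
        for i, chunk in enumerate(chunks):
            start = int(chunk[0])
            end = int(chunks[i + 1][0]) if i + 1 < len(chunks) else int(chunk[-1])
            windows.append((start, end))
        return cls(windows=tuple(windows))


@dataclass(frozen=True)
class ElevationBands:
    """Altitudinal belts (m a.s.l.); boundaries belong to the upper band."""

    bands: tuple[tuple[str, float, float], ...] = (
        ("mountain", 1400.0, 1900.0),
        ("sub-alpine", 1900.0, 2300.0),
        ("alpine", 2300.0, 2700.0),
        ("nival", 2700.0, 4000.0),
    )

    @property
    def names(self) -> list[str]:
        return [n for n, _, _ in self.bands]


def fill_gaps(traj: np.ndarray) -> np.ndarray:
    """Rule i: fill missing entries from up to 3 preceding + 3 following
    non-missing neighbours (simultaneously, from the original labels).

    Mode ties go to the class of the temporally nearest neighbour, the
    earlier one at equal distance.  A gap with an all-missing window stays
    missing.
    """
    traj = np.asarray(traj)
    out = traj.copy()
    n = len(traj)
    for t in np.nonzero(traj == MISSING)[0]:
        lo, hi = max(0, t - 3), min(n, t + 4)
        offsets = [k for k in range(lo, hi) if k != t and traj[k] != MISSING]
        if not offsets:
            continue
        counts = Counter(traj[k] for k in offsets)
        best = max(counts.values())
        tied = {c for c, v in counts.items() if v == best}
        if len(tied) == 1:
            out[t] = tied.pop()
        else:
            # nearest neighbour holding a tied class; earlier wins at equal distance
            offsets.sort(key=lambda k: (abs(k - t), k))
            out[t] = next(traj[k] for k in offsets if traj[k] in tied)
    return out


def enforce_water_persistence(traj: np.ndarray, water_code: int = WATER_CODE) -> np.ndarray:
    """Rule ii: a pixel that is water for more than half the series is water
    throughout (strictly more than half)."""
    traj = np.asarray(traj)
    if np.count_nonzero(traj == water_code) * 2 > len(traj):
        return np.full_like(traj, water_code)
    return traj.copy()


def remove_singletons(traj: np.ndarray) -> np.ndarray:
    """Rule iii: classes occurring in exactly one year are reassigned to the
    modal class among the non-singleton classes.

    Mode ties go to the lower class code.  If every class is a singleton
    (all labels distinct) the trajectory is left unchanged.  Requires a
    gap-free trajectory (run after rule i); remaining gaps are ignored.
    """
    traj = np.asarray(traj)
    counts = Counter(int(v) for v in traj if v != MISSING)
    singles = {c for c, v in counts.items() if v == 1}
    keepers = {c: v for c, v in counts.items() if v > 1}
    if not singles or not keepers:
        return traj.copy()
    best = max(keepers.values())
    modal = min(c for c, v in keepers.items() if v == best)
    out = traj.copy()
    out[np.isin(traj, list(singles))] = modal
    return out


def apply_rules(traj: np.ndarray, water_code: int = WATER_CODE) -> np.ndarray:
    """Full rule chain i -> ii -> iii on one trajectory."""
    return remove_singletons(enforce_water_persistence(fill_gaps(traj), water_code))


def apply_rules_series(series: ClassMapSeries, water_code: int = WATER_CODE) -> ClassMapSeries:
    """Apply the rule chain to every pixel of an annual series."""
    stack = extract_trajectories(series)
    T, h, w = stack.shape
    flat = stack.reshape(T, -1)
    out = flat.copy()
    # rule i only touches pixels with gaps; rules ii-iii are cheap per pixel
    has_gap = (flat == MISSING).any(axis=0)
    for i in np.nonzero(has_gap)[0]:
        out[:, i] = fill_gaps(flat[:, i])
    water_count = (out == water_code).sum(axis=0)
    persistent = water_count * 2 > T
    out[:, persistent] = water_code
    for i in range(flat.shape[1]):
        if persistent[i]:
            continue
        col = out[:, i]
        # cheap pre-check: any label occurring exactly once?
        vals, cnts = np.unique(col[col != MISSING], return_counts=True)
        if (cnts == 1).any() and (cnts > 1).any():
            out[:, i] = remove_singletons(col)
    return series_from_trajectories(
        out.reshape(T, h, w), series.years, series.maps[0], series.level, series.legend
    )


def decadal_aggregate(series: ClassMapSeries, scheme: AggregationScheme) -> ClassMapSeries:
    """Per-window modal class per pixel; mode ties take the class observed
    in the latest year of the window."""
    stack = extract_trajectories(series)
    out_maps = []
    out_years = []
    for window in scheme.windows:
        yrs = scheme.years_in(window, series.years)
        if not yrs:
            raise ValidationError(f"window {window} contains no series years")
        idx = [series.years.index(y) for y in yrs]
        sub = stack[idx]  # (k, h, w)
        k = sub.shape[0]
        codes = [c for c in np.unique(sub) if c != MISSING]
        counts = {c: (sub == c).sum(axis=0) for c in codes}
        best = (
            np.max(np.stack(list(counts.values())), axis=0)
            if codes else np.zeros(sub.shape[1:], dtype=int)
        )
        winner = np.zeros(sub.shape[1:], dtype=np.int64)
        # scan window years latest-first; first tied class encountered wins
        assigned = np.zeros(sub.shape[1:], dtype=bool)
        for i in range(k - 1, -1, -1):
            lab = sub[i]
            count_of_lab = np.zeros(sub.shape[1:], dtype=int)
            for c in codes:
                count_of_lab[lab == c] = counts[c][lab == c]
            is_tied = ~assigned & (lab != MISSING) & (count_of_lab == best) & (best > 0)
            winner[is_tied] = lab[is_tied]
            assigned |= is_tied
        out_maps.append(winner)
        out_years.append(window[0])
    agg = np.stack(out_maps)
    return series_from_trajectories(
        agg, out_years, series.maps[0], series.level, series.legend
    )


def classify_trajectory(traj: np.ndarray) -> str:
    """Type a gap-free trajectory as stable / transition / mixed.

    Stable: one class throughout (length < 2 is stable by convention).
    Transition: exactly one change point and exactly two classes (a
    unidirectional A...AB...B shift).  Mixed: anything else.
    """
    traj = np.asarray(traj)
    if len(traj) < 2 or len(np.unique(traj)) == 1:
        return "stable"
    changes = int(np.count_nonzero(traj[1:] != traj[:-1]))
    if changes == 1 and len(np.unique(traj)) == 2:
        return "transition"
    return "mixed"


def trajectory_type_map(series: ClassMapSeries) -> Grid:
    """Per-pixel trajectory type: 1 stable, 2 transition, 3 mixed, 0 missing."""
    stack = extract_trajectories(series)
    T = stack.shape[0]
    flat = stack.reshape(T, -1)
    out = np.zeros(flat.shape[1], dtype=np.uint8)
    complete = (flat != MISSING).all(axis=0)
    changes = (flat[1:] != flat[:-1]).sum(axis=0)
    n_classes = np.array([len(np.unique(col)) for col in flat.T])
    out[complete & ((changes == 0) | (T < 2))] = 1
    out[complete & (changes == 1) & (n_classes == 2)] = 2
    out[complete & (out == 0)] = 3
    return series.maps[0].like(out.reshape(series.shape), nodata=0)


@dataclass
class TransitionMatrix:
    """Class-to-class change accounting over transition-typed pixels."""

    counts: pd.DataFrame  # from-class rows x to-class columns, pixel counts
    pixel_area_ha: float
    min_pct: float = 1.0

    @property
    def area_ha(self) -> pd.DataFrame:
        return self.counts * self.pixel_area_ha

    @property
    def percent(self) -> pd.DataFrame:
        total = self.counts.to_numpy().sum()
        if total == 0:
            return self.counts * 0.0
        return 100.0 * self.counts / total

    def report(self) -> pd.DataFrame:
        """Long-format (from, to, area_ha, pct), transitions below
        ``min_pct`` percent of the changed area excluded."""
        pct = self.percent
        rows = []
        for f in self.counts.index:
            for t in self.counts.columns:
                if self.counts.loc[f, t] > 0 and pct.loc[f, t] >= self.min_pct:
                    rows.append(
                        {
                            "from": f,
                            "to": t,
                            "area_ha": self.area_ha.loc[f, t],
                            "pct": pct.loc[f, t],
                        }
                    )
        return pd.DataFrame(rows, columns=["from", "to", "area_ha", "pct"])


def transition_matrix(
    first: Grid,
    last: Grid,
    mask: np.ndarray,
    min_pct: float = 1.0,
) -> TransitionMatrix:
    """Count first->last class pairs over the masked (transition) pixels."""
    if first.shape != last.shape or mask.shape != first.shape:
        raise ValidationError("first/last/mask must be co-registered")
    if not mask.any():
        warnings.warn("empty transition mask; matrix is empty")
    f = np.asarray(first.values)[mask]
    t = np.asarray(last.values)[mask]
    codes = sorted(set(np.unique(f)) | set(np.unique(t)))
    counts = pd.DataFrame(0, index=codes, columns=codes, dtype=float)
    for (a, b), n in Counter(zip(f.tolist(), t.tolist())).items():
        counts.loc[a, b] = n
    return TransitionMatrix(
        counts=counts, pixel_area_ha=first.pixel_area_ha, min_pct=min_pct
    )


def change_rate(
    series: ClassMapSeries,
    class_code: int,
    region_mask: np.ndarray | None = None,
    band_mask: np.ndarray | None = None,
    method: str = "ols",
) -> float:
    """Rate of change of a class's area, in hectares per year.

    Annual class area within the optional region/elevation masks is
    regressed on year (ordinary least squares); ``method='endpoint'``
    instead divides the first-to-last area difference by the year span.
    """
    if len(series) < 2:
        raise ValidationError("need at least two years")
    area_px = series.maps[0].pixel_area_ha
    sel = np.ones(series.shape, dtype=bool)
    if region_mask is not None:
        sel &= region_mask
    if band_mask is not None:
        sel &= band_mask
    areas = np.array(
        [np.count_nonzero((np.asarray(g.values) == class_code) & sel) * area_px
         for g in series.maps]
    )
    if not areas.any():
        warnings.warn(f"class {class_code} absent in every year; rate 0")
        return 0.0
    years = np.asarray(series.years, dtype=float)
    if method == "endpoint":
        return float((areas[-1] - areas[0]) / (years[-1] - years[0]))
    slope, _ = np.polyfit(years, areas, 1)
    return float(slope)


def trend(values, years=None) -> tuple[float, float, str]:
    """OLS trend of an annual series: (slope per year, p-value, stars).

    Stars follow the usual convention: ``*`` p < 0.05, ``**`` p < 0.01,
    ``***`` p < 0.001; missing values are dropped pairwise.  A perfectly
    linear series (zero residual) gets p = 0 for a non-zero slope.
    """
    values = np.asarray(values, dtype=float)
    years = (
        np.arange(len(values), dtype=float) if years is None
        else np.asarray(years, dtype=float)
    )
    ok = np.isfinite(values)
    values, years = values[ok], years[ok]
    if len(values) < 3:
        raise ValidationError("trend needs at least three non-missing values")
    if np.ptp(values) == 0:
        return 0.0, 1.0, ""
    with np.errstate(invalid="ignore", divide="ignore"):
        fit = _stats.linregress(years, values)
    slope, p = float(fit.slope), float(fit.pvalue)
    if not np.isfinite(p):
        p = 0.0 if slope != 0 else 1.0
    stars = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
    return slope, p, stars


def elevation_stratify(dtm: Grid, bands: ElevationBands = ElevationBands()) -> Grid:
    """Label each pixel with its altitudinal belt (1-based, 0 outside).

    Belt boundaries are half-open [low, high), so a boundary elevation
    belongs to the upper belt.
    """
    z = np.asarray(dtm.values, dtype=float)
    out = np.zeros(z.shape, dtype=np.uint8)
    for i, (_, low, high) in enumerate(bands.bands, start=1):
        out[(z >= low) & (z < high)] = i
    out[~dtm.valid_mask()] = 0
    return dtm.like(out, nodata=0)
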