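"""Thematic accuracy assessment and patch-structure diagnostics.

Confusion matrices are oriented rows = predicted, columns = reference
(stated in every output), so producer's accuracy (PA, per-class recall
against reference totals) reads down a column and user's accuracy (UA,
precision against predicted totals) along a row.  Overall metrics are
overall accuracy (OA), balanced accuracy (BA, mean of per-class
(recall + specificity)/2), Cohen's kappa and a weighted accuracy (WA,
class-weighted recall with inverse-prevalence weights by default, so rare
classes are not swamped).  Per-class metrics are PA, UA, F1 and the true
skill statistic (TSS = recall + specificity - 1, one-vs-rest).  Undefined
metrics propagate as NaN, never silently as zero.

Patch metrics (8-connected patches, 4-connected edges) support the
classic observation that large, cohesive patches classify better than
fragmented ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats
from skimage import measure

from .core import Grid, ValidationError

__all__ = [
    "ConfusionMatrix",
    "PatchStats",
    "confusion",
    "overall_metrics",
    "class_metrics",
    "patch_metrics",
    "accuracy_structure_correlation",
]


@dataclass
class ConfusionMatrix:
    """Predicted-vs-reference count table; rows predicted, columns reference."""

    counts: np.ndarray
    classes: list[int]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValidationError("confusion matrix must be square over its classes")
        if (self.counts < 0).any():
            raise ValidationError("confusion counts must be non-negative")

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.classes, name="predicted"),
            columns=pd.Index(self.classes, name="reference"),
        )


def confusion(pred: Grid | np.ndarray, ref: Grid | np.ndarray) -> ConfusionMatrix:
    """Tally predicted vs reference labels over jointly valid pixels."""
    pv = np.asarray(pred.values if isinstance(pred, Grid) else pred)
    rv = np.asarray(ref.values if isinstance(ref, Grid) else ref)
    if pv.shape != rv.shape:
        raise ValidationError("predicted and reference must be co-registered")
    valid = np.ones(pv.shape, dtype=bool)
    for arr, src in ((pv, pred), (rv, ref)):
        nodata = src.nodata if isinstance(src, Grid) else 0
        if nodata is not None:
            valid &= arr != nodata
    if not valid.any():
        raise ValidationError("no jointly valid samples")
    p, r = pv[valid].ravel(), rv[valid].ravel()
    classes = sorted(set(np.unique(p)) | set(np.unique(r)))
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)))
    np.add.at(counts, ([index[x] for x in p], [index[x] for x in r]), 1)
    return ConfusionMatrix(counts=counts, classes=[int(c) for c in classes])


def _margins(cm: ConfusionMatrix):
    c = cm.counts
    return c.sum(axis=1), c.sum(axis=0), np.diag(c)  # row (pred), col (ref), diag


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(np.shape(num), np.nan)
    ok = np.asarray(den) > 0
    out[ok] = np.asarray(num)[ok] / np.asarray(den)[ok]
    return out


def _recall_specificity(cm: ConfusionMatrix) -> tuple[np.ndarray, np.ndarray]:
    rows, cols, diag = _margins(cm)
    n = cm.n
    recall = _safe_div(diag, cols)
    tp = diag
    fp = rows - diag
    tn = n - cols - fp
    specificity = _safe_div(tn, n - cols)
    return recall, specificity


def overall_metrics(
    cm: ConfusionMatrix, class_weights: dict[int, float] | None = None
) -> dict[str, float]:
    """OA, BA, Cohen's kappa and weighted accuracy.

    WA is a weighted mean of per-class recall; default weights are inverse
    reference prevalence (normalised), up-weighting rare classes.  Kappa is
    undefined (NaN) when chance agreement is 1 (a single observed class).
    """
    if cm.n <= 0:
        raise ValidationError("empty confusion matrix")
    rows, cols, diag = _margins(cm)
    n = cm.n
    oa = diag.sum() / n
    recall, specificity = _recall_specificity(cm)
    ba = float(np.nanmean((recall + specificity) / 2.0))
    pe = float((rows * cols).sum() / n**2)
    kappa = np.nan if pe >= 1.0 else (oa - pe) / (1.0 - pe)

    present = cols > 0
    if class_weights is None:
        w = np.zeros(len(cm.classes))
        w[present] = 1.0 / (cols[present] / n)
    else:
        w = np.array([class_weights.get(c, 0.0) for c in cm.classes], dtype=float)
        w[~present] = 0.0
    if w.sum() <= 0:
        wa = np.nan
    else:
        w = w / w.sum()
        wa = float(np.nansum(w * np.where(present, recall, 0.0)))
    return {"oa": float(oa), "ba": ba, "kappa": float(kappa), "wa": wa}


def class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class PA, UA, F1 and TSS; empty margins yield NaN."""
    if cm.n <= 0:
        raise ValidationError("empty confusion matrix")
    rows, cols, diag = _margins(cm)
    pa = _safe_div(diag, cols)
    ua = _safe_div(diag, rows)
    with np.errstate(invalid="ignore"):
        f1 = np.where((pa + ua) > 0, 2 * pa * ua / (pa + ua), np.nan)
    recall, specificity = _recall_specificity(cm)
    tss = recall + specificity - 1.0
    return pd.DataFrame(
        {"pa": pa, "ua": ua, "f1": f1, "tss": tss},
        index=pd.Index(cm.classes, name="class"),
    )


@dataclass
class PatchStats:
    """Per-class landscape structure summary."""

    table: pd.DataFrame  # index class; n_patches, mean_patch_area_ha,
    #                      total_edge_m, mean_shape_index


def patch_metrics(class_map: Grid, classes: list[int] | None = None) -> PatchStats:
    """Patch count, mean patch area, edge length and mean shape index per class.

    Patches are 8-connected components; edges count 4-neighbour faces
    against a different class or the map border, at 30 m (one pixel side)
    each.  The shape index of a patch is P / (2 sqrt(pi A)), 1 for a disc
    and about 1.13 for a square.
    """
    values = np.asarray(class_map.values)
    px = class_map.transform.pixel_size
    area_ha = class_map.pixel_area_ha
    if classes is None:
        classes = sorted(set(np.unique(values)) - {0, class_map.nodata})
    records = []
    for c in classes:
        mask = values == c
        npix = int(mask.sum())
        if npix == 0:
            records.append(
                {"class": c, "n_patches": 0, "mean_patch_area_ha": 0.0,
                 "total_edge_m": 0.0, "mean_shape_index": np.nan}
            )
            continue
        labels = measure.label(mask, connectivity=2)
        n_patches = int(labels.max())
        padded = np.pad(mask, 1)
        faces = 0
        for shift_axis in (0, 1):
            diff = np.diff(padded.astype(np.int8), axis=shift_axis)
            faces += int(np.abs(diff).sum())
        total_edge = faces * px
        shape_idx = []
        for lab in range(1, n_patches + 1):
            pm = labels == lab
            pp = np.pad(pm, 1)
            pfaces = 0
            for shift_axis in (0, 1):
                pfaces += int(np.abs(np.diff(pp.astype(np.int8), axis=shift_axis)).sum())
            perim = pfaces * px
            area = pm.sum() * px * px
            shape_idx.append(perim / (2.0 * np.sqrt(np.pi * area)))
        records.append(
            {
                "class": c,
                "n_patches": n_patches,
                "mean_patch_area_ha": npix * area_ha / n_patches,
                "total_edge_m": total_edge,
                "mean_shape_index": float(np.mean(shape_idx)),
            }
        )
    return PatchStats(table=pd.DataFrame(records).set_index("class"))


def accuracy_structure_correlation(
    metrics: pd.DataFrame, patches: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r between each accuracy metric and each landscape metric,
    across classes, pairwise-complete; NaN below three complete pairs."""
    joined = metrics.join(patches, how="inner")
    if len(joined) < 3:
        warnings.warn("fewer than three classes with both tables defined")
    out = pd.DataFrame(index=metrics.columns, columns=patches.columns, dtype=float)
    for m in metrics.columns:
        for s in patches.columns:
            pair = joined[[m, s]].dropna()
            if len(pair) < 3 or pair[m].nunique() < 2 or pair[s].nunique() < 2:
                out.loc[m, s] = np.nan
                continue
            out.loc[m, s] = float(_stats.pearsonr(pair[m], pair[s]).statistic)
    return out
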