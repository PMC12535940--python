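"""Predictor selection: ROC-AUC screening, shadow-feature confirmation,
and Kendall correlation pruning.

The three stages run in a fixed order and each returns a subset of its
input: (1) predictors whose direction-free one-vs-rest AUC reaches a
threshold for at least one class survive the screen; (2) a Boruta-style
shadow-feature test confirms predictors whose random-forest importance
beats the best permuted copy more often than chance; (3) highly
rank-correlated pairs are thinned, keeping the member with the stronger
importance record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .core import ValidationError

__all__ = [
    "PredictorReport",
    "auc_screen",
    "boruta_select",
    "correlation_prune",
    "select_predictors",
]


@dataclass
class PredictorReport:
    """Audit trail of the selection pipeline for every candidate predictor."""

    auc: pd.DataFrame | None = None  # predictors x classes, direction-free AUC
    screened: list[str] = field(default_factory=list)
    boruta: pd.DataFrame | None = None  # verdict, hits, median importance
    confirmed: list[str] = field(default_factory=list)
    kendall: pd.DataFrame | None = None  # pairwise tau over the confirmed set
    final: list[str] = field(default_factory=list)


def _table_xy(train: pd.DataFrame, predictors: list[str]) -> tuple[np.ndarray, np.ndarray]:
    X = train[predictors].to_numpy(dtype=float)
    y = train["label"].to_numpy()
    return X, y


def auc_screen(
    train: pd.DataFrame,
    predictors: list[str],
    threshold: float = 0.75,
) -> tuple[list[str], pd.DataFrame]:
    """One-vs-rest AUC per (predictor, class); keep predictors separating
    at least one class.

    AUC is direction-free, max(AUC, 1 - AUC): a predictor consistently low
    for a class separates it exactly as well as one consistently high.
    Classes with fewer than two samples, or classes absent a counter-class,
    are skipped.
    """
    classes = sorted(train["label"].unique())
    if len(classes) < 2:
        raise ValidationError("AUC screening needs at least two classes")
    X, y = _table_xy(train, predictors)
    rows = {}
    for j, name in enumerate(predictors):
        rows[name] = {}
        for c in classes:
            pos = y == c
            if pos.sum() < 2 or (~pos).sum() < 2:
                rows[name][c] = np.nan
                continue
            auc = roc_auc_score(pos, X[:, j])
            rows[name][c] = max(auc, 1.0 - auc)
    report = pd.DataFrame(rows).T  # predictors x classes
    kept = [p for p in predictors if np.nanmax(report.loc[p].to_numpy()) >= threshold]
    return kept, report


def _forest(rf_params: dict | None, seed: int) -> RandomForestClassifier:
    params = dict(
        n_estimators=100, min_samples_leaf=4, max_features="sqrt", n_jobs=1
    )
    params.update(rf_params or {})
    params["random_state"] = seed
    return RandomForestClassifier(**params)


def boruta_select(
    train: pd.DataFrame,
    predictors: list[str],
    rf_params: dict | None = None,
    max_runs: int = 100,
    alpha: float = 0.01,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Shadow-feature relevance test.

    Each run appends a permuted "shadow" copy of every predictor, fits a
    random forest, and records a hit for every real predictor whose Gini
    importance exceeds the maximum shadow importance.  After ``max_runs``
    runs a two-sided binomial test of the hit count against p = 0.5 at
    level ``alpha`` classifies predictors as confirmed or rejected;
    leftover tentatives are resolved by comparing their median importance
    with the median of the per-run maximum shadow importance, ties going
    to rejection.
    """
    if not predictors:
        raise ValidationError("empty predictor set")
    rng = np.random.default_rng(seed)
    X, y = _table_xy(train, predictors)
    n, p = X.shape
    hits = np.zeros(p, dtype=int)
    imp_history = np.empty((max_runs, p))
    shadow_max_history = np.empty(max_runs)
    for run in range(max_runs):
        shadows = np.empty_like(X)
        for j in range(p):
            shadows[:, j] = rng.permutation(X[:, j])
        Xa = np.hstack([X, shadows])
        forest = _forest(rf_params, seed=int(rng.integers(2**31 - 1)))
        forest.fit(Xa, y)
        imp = forest.feature_importances_
        real, shadow = imp[:p], imp[p:]
        shadow_max = shadow.max()
        hits += real > shadow_max
        imp_history[run] = real
        shadow_max_history[run] = shadow_max

    verdicts, tentative = [], []
    for j in range(p):
        pval = stats.binomtest(int(hits[j]), max_runs, 0.5).pvalue
        if pval < alpha and hits[j] > max_runs / 2:
            verdict, was_tentative = "confirmed", False
        elif pval < alpha and hits[j] < max_runs / 2:
            verdict, was_tentative = "rejected", False
        else:
            med = np.median(imp_history[:, j])
            med_shadow = np.median(shadow_max_history)
            verdict = "confirmed" if med > med_shadow else "rejected"
            was_tentative = True
        verdicts.append(verdict)
        tentative.append(was_tentative)
    report = pd.DataFrame(
        {
            "predictor": predictors,
            "hits": hits,
            "runs": max_runs,
            "median_importance": np.median(imp_history, axis=0),
            "median_shadow_max": np.median(shadow_max_history),
            "verdict": verdicts,
            "tentative": tentative,
        }
    ).set_index("predictor")
    confirmed = [p_ for p_, v in zip(predictors, verdicts) if v == "confirmed"]
    return confirmed, report


def correlation_prune(
    train: pd.DataFrame,
    predictors: list[str],
    tau_threshold: float = 0.9,
    importance: pd.Series | None = None,
    auc_report: pd.DataFrame | None = None,
    max_rows: int = 10_000,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Greedy multicollinearity pruning on tie-adjusted Kendall tau-b.

    While any pair exceeds ``tau_threshold`` in |tau|, the worst pair is
    examined and the member with the lower Boruta median importance
    (fallback: lower best per-class AUC, then lexicographic order) is
    dropped.  Tau is computed on a seeded subsample of at most
    ``max_rows`` rows for tractability.
    """
    if not predictors:
        raise ValidationError("empty predictor set")
    data = train[predictors]
    if len(data) > max_rows:
        data = data.sample(max_rows, random_state=seed)
    X = data.to_numpy(dtype=float)

    p = len(predictors)
    tau = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            t = stats.kendalltau(X[:, i], X[:, j]).statistic
            tau[i, j] = tau[j, i] = 0.0 if np.isnan(t) else t
    tau_df = pd.DataFrame(tau, index=predictors, columns=predictors)

    def rank_key(name: str) -> tuple:
        imp = float(importance.get(name, -np.inf)) if importance is not None else -np.inf
        auc = (
            float(np.nanmax(auc_report.loc[name].to_numpy()))
            if auc_report is not None and name in auc_report.index
            else -np.inf
        )
        return (imp, auc, [-ord(ch) for ch in name])

    kept = list(predictors)
    while True:
        worst, worst_pair = 0.0, None
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                t = abs(tau_df.loc[kept[i], kept[j]])
                if t > worst:
                    worst, worst_pair = t, (kept[i], kept[j])
        if worst_pair is None or worst <= tau_threshold:
            break
        a, b = worst_pair
        drop = a if rank_key(a) < rank_key(b) else b
        kept.remove(drop)
    return kept, tau_df


def select_predictors(
    train: pd.DataFrame,
    predictors: list[str],
    auc_threshold: float = 0.75,
    tau_threshold: float = 0.9,
    boruta_runs: int = 100,
    boruta_alpha: float = 0.01,
    rf_params: dict | None = None,
    seed: int = 0,
) -> PredictorReport:
    """Full AUC -> Boruta -> Kendall pipeline; each stage subsets the last."""
    report = PredictorReport()
    screened, report.auc = auc_screen(train, predictors, threshold=auc_threshold)
    report.screened = screened
    if not screened:
        warnings.warn("AUC screen discarded every predictor")
        return report
    confirmed, report.boruta = boruta_select(
        train, screened, rf_params=rf_params, max_runs=boruta_runs,
        alpha=boruta_alpha, seed=seed,
    )
    report.confirmed = confirmed
    if not confirmed:
        warnings.warn("Boruta rejected every screened predictor")
        return report
    final, report.kendall = correlation_prune(
        train,
        confirmed,
        tau_threshold=tau_threshold,
        importance=report.boruta["median_importance"],
        auc_report=report.auc,
        seed=seed,
    )
    report.final = final
    return report
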