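"""Two-level random-forest ensemble classification.

Per year, five random forests are trained on the same pure-pixel table
with distinct seeds and aggregated by per-pixel majority vote into a land
cover (L1) map.  Habitat (L2) classification is hierarchical: within each
vegetated L1 class a separate ensemble, trained only on that class's
habitats, labels only the pixels the L1 map assigned to it — so an
emitted habitat label can never contradict its land-cover parent.

Default hyperparameters: 100 trees, 16 candidate variables per split
(clamped to the predictor count), minimum terminal node size 4 and a 0.51
bootstrap sample fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .core import Grid, Legend, ValidationError

__all__ = [
    "RfHyperparams",
    "EnsembleModel",
    "train_ensemble",
    "predict_majority",
    "hierarchical_classify",
    "member_seeds",
]

N_MEMBERS = 5


@dataclass(frozen=True)
class RfHyperparams:
    n_trees: int = 100
    mtry: int = 16
    min_node_size: int = 4
    sample_fraction: float = 0.51

    def __post_init__(self) -> None:
        if min(self.n_trees, self.mtry, self.min_node_size) <= 0:
            raise ValidationError("hyperparameters must be positive")
        if not 0 < self.sample_fraction <= 1:
            raise ValidationError("sample_fraction must lie in (0, 1]")


def member_seeds(master_seed: int, n: int = N_MEMBERS) -> list[int]:
    """Spawn ``n`` distinct member seeds deterministically from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]
    if len(set(seeds)) != n:  # astronomically unlikely; keep the invariant hard
        seeds = [(s + i) % (2**31 - 1) for i, s in enumerate(seeds)]
    return seeds


@dataclass
class EnsembleModel:
    """Five fitted forests plus the metadata needed to replay a prediction."""

    level: str
    members: list[RandomForestClassifier]
    seeds: list[int]
    predictors: list[str]
    classes: list[int]
    params: RfHyperparams
    parent_class: int | None = None

    def __post_init__(self) -> None:
        if len(self.members) != N_MEMBERS:
            raise ValidationError(f"ensemble must have {N_MEMBERS} members")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValidationError("member seeds must be distinct")


def train_ensemble(
    train,
    predictors: list[str],
    params: RfHyperparams = RfHyperparams(),
    master_seed: int = 0,
    level: str = "L1",
    parent_class: int | None = None,
) -> EnsembleModel:
    """Fit the five-member ensemble on one training table.

    All members see the same rows; only their random streams (bootstrap and
    per-split feature sampling) differ, so a rerun with the same master
    seed reproduces every prediction bitwise.
    """
    missing = [p for p in predictors if p not in train.columns]
    if missing:
        raise ValidationError(f"training table lacks predictors: {missing}")
    y = train["label"].to_numpy()
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValidationError("training table must contain at least two classes")
    X = train[predictors].to_numpy(dtype=float)

    mtry = params.mtry
    if mtry > len(predictors):
        warnings.warn(
            f"mtry={mtry} exceeds {len(predictors)} predictors; clamping"
        )
        mtry = len(predictors)

    seeds = member_seeds(master_seed)
    members = []
    for seed in seeds:
        forest = RandomForestClassifier(
            n_estimators=params.n_trees,
            max_features=mtry,
            min_samples_leaf=params.min_node_size,
            bootstrap=True,
            max_samples=params.sample_fraction,
            random_state=seed,
            n_jobs=1,
        )
        forest.fit(X, y)
        members.append(forest)
    return EnsembleModel(
        level=level, members=members, seeds=seeds, predictors=predictors,
        classes=classes, params=params, parent_class=parent_class,
    )


def _majority(votes: np.ndarray, proba: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Majority vote with deterministic tie-breaks.

    ``votes``: (n_members, n_samples) class labels; ``proba``: (n_samples,
    n_classes) mean ensemble probabilities aligned with ``classes``
    (ascending).  Ties go to the higher mean probability, then the lower
    class code.
    """
    n_classes = len(classes)
    code_to_idx = {c: i for i, c in enumerate(classes)}
    tally = np.zeros((votes.shape[1], n_classes))
    for member_votes in votes:
        idx = np.vectorize(code_to_idx.__getitem__)(member_votes)
        np.add.at(tally, (np.arange(votes.shape[1]), idx), 1.0)
    # probability term < 1 vote, so it only separates exact vote ties;
    # argmax then favours the lowest class code on residual ties
    key = tally + 0.5 * proba
    return classes[np.argmax(key, axis=1)]


def predict_majority(
    model: EnsembleModel,
    predictors: dict[str, Grid],
    valid: np.ndarray | None = None,
) -> Grid:
    """Predict a class grid by per-pixel majority vote of the five members.

    A pixel that is nodata in any predictor is nodata (0) in the output.
    """
    missing = [p for p in model.predictors if p not in predictors]
    if missing:
        raise ValidationError(f"missing predictor grids: {missing}")
    template = predictors[model.predictors[0]]
    mask = np.ones(template.shape, dtype=bool)
    for name in model.predictors:
        mask &= predictors[name].valid_mask()
    if valid is not None:
        mask &= valid

    out = np.zeros(template.shape, dtype=np.uint16)
    if not mask.any():
        return template.like(out, nodata=0)
    X = np.stack(
        [np.asarray(predictors[n].values, dtype=float)[mask] for n in model.predictors],
        axis=1,
    )
    classes = np.asarray(model.classes)
    votes = np.stack([m.predict(X) for m in model.members])
    proba = np.zeros((X.shape[0], len(classes)))
    for m in model.members:
        aligned = np.zeros_like(proba)
        for i, c in enumerate(m.classes_):
            aligned[:, np.searchsorted(classes, c)] = m.predict_proba(X)[:, i]
        proba += aligned
    proba /= len(model.members)
    out[mask] = _majority(votes, proba, classes)
    return template.like(out, nodata=0)


def hierarchical_classify(
    l1_map: Grid,
    l2_models: dict[int, EnsembleModel],
    predictors: dict[str, Grid],
    legend: Legend | None = None,
) -> Grid:
    """Label habitats only within their land-cover parent class.

    Pixels whose L1 class has no habitat model (rocks, snow, water,
    wetland) carry no L2 label (0).  The parent of every emitted L2 label
    equals the pixel's L1 label by construction; this is asserted.
    """
    out = np.zeros(l1_map.shape, dtype=np.uint16)
    l1 = np.asarray(l1_map.values)
    for parent, model in l2_models.items():
        if legend is not None:
            bad = [c for c in model.classes if legend.parent_of(c) != parent]
            if bad:
                raise ValidationError(
                    f"model for parent {parent} predicts foreign habitats {bad}"
                )
        zone = l1 == parent
        if not zone.any():
            continue
        pred = predict_majority(model, predictors, valid=zone)
        out[zone] = pred.values[zone]
    if legend is not None:
        emitted = out > 0
        parents = np.zeros_like(out)
        for code in np.unique(out[emitted]):
            parents[out == code] = legend.parent_of(int(code))
        assert np.array_equal(parents[emitted], l1[emitted]), "hierarchy violated"
    return l1_map.like(out, nodata=0)
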