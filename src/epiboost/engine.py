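"""Gradient-boosted tree engine: sequential tuning, ranking, fit/predict.

The classifier is an XGBoost binary-logistic ensemble.  Eight hyperparameters
are exposed; their default candidate lists are the published search ranges:

====================  ==============================================
number of trees       50, 100, 150, 200, 250, 300
tree depth            2, 4, 6, 8
learning rate         0.001, 0.01, 0.1
subsample rate        0.1 .. 1.0 (step 0.1), without replacement
min child weight      0, 0.1, 0.2, 0.5, 0.6, 0.7, 0.8, 0.9, 1, 2, 3, 4, 5
gamma                 0, 0.1, .., 0.9, 1, 4, 9
alpha (L1)            1e-5, 1e-2, 0.1, 1, 2, 5, 100
scale positive weight 0.56 (controls/cases of the reference cohort), 1
====================  ==============================================

Tuning is sequential rather than exhaustive: the (trees, depth, learning
rate) triple is grid-searched jointly under stratified 5-fold CV first, then
subsample rate, min child weight, gamma, alpha and scale positive weight are
optimized one at a time, each stage keeping the winners of earlier stages
fixed.  The selection criterion is mean cross-validated average precision
(log-loss is available as an alternative).  Ties break toward the more
regularized model: fewer trees, shallower depth, lower learning rate, larger
alpha, larger gamma.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .cohort import CombinedFeatureMatrix, FeatureDescriptor
from .metrics import average_precision_score

__all__ = [
    "HyperParams",
    "HyperParamGrid",
    "RankedFeature",
    "RankedFeatureList",
    "FittedModel",
    "tune_sequential",
    "rank_features",
    "fit",
    "predict",
]


class EngineError(ValueError):
    pass


@dataclass(frozen=True)
class HyperParams:
    n_trees: int = 150
    tree_depth: int = 2
    learning_rate: float = 0.01
    subsample_rate: float = 0.4
    min_child_weight: float = 0.0
    gamma: float = 0.0
    alpha: float = 2.0
    scale_pos_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.tree_depth < 1:
            raise EngineError("n_trees and tree_depth must be positive")
        if self.learning_rate <= 0:
            raise EngineError("learning_rate must be positive")
        if not (0 < self.subsample_rate <= 1):
            raise EngineError("subsample_rate must lie in (0, 1]")
        if min(self.min_child_weight, self.gamma, self.alpha) < 0:
            raise EngineError("min_child_weight, gamma and alpha must be >= 0")
        if self.scale_pos_weight <= 0:
            raise EngineError("scale_pos_weight must be positive")

    def to_xgb_kwargs(self, seed: int) -> dict:
        return dict(
            n_estimators=self.n_trees,
            max_depth=self.tree_depth,
            learning_rate=self.learning_rate,
            subsample=self.subsample_rate,
            sampling_method="uniform",  # without replacement, per tree
            min_child_weight=self.min_child_weight,
            gamma=self.gamma,
            reg_alpha=self.alpha,
            reg_lambda=1.0,
            scale_pos_weight=self.scale_pos_weight,
            objective="binary:logistic",
            tree_method="hist",
            n_jobs=1,
            random_state=int(seed) % (2**31),
            eval_metric="logloss",
            verbosity=0,
        )

    #: tie-break sort key — smaller is preferred (more regularized model)
    def complexity_key(self) -> tuple:
        return (
            self.n_trees,
            self.tree_depth,
            self.learning_rate,
            -self.alpha,
            -self.gamma,
        )


@dataclass
class HyperParamGrid:
    n_trees: Sequence[int] = (50, 100, 150, 200, 250, 300)
    tree_depth: Sequence[int] = (2, 4, 6, 8)
    learning_rate: Sequence[float] = (0.001, 0.01, 0.1)
    subsample_rate: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    min_child_weight: Sequence[float] = (
        0, 0.1, 0.2, 0.5, 0.6, 0.7, 0.8, 0.9, 1, 2, 3, 4, 5,
    )
    gamma: Sequence[float] = (0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1, 4, 9)
    alpha: Sequence[float] = (1e-5, 1e-2, 0.1, 1, 2, 5, 100)
    scale_pos_weight: Sequence[float] = (0.56, 1)

    def __post_init__(self) -> None:
        for name in self.stage_order():
            if not len(getattr(self, name)):
                raise EngineError(f"grid list {name!r} must be non-empty")
        for extra in ("n_trees", "tree_depth", "learning_rate"):
            if not len(getattr(self, extra)):
                raise EngineError(f"grid list {extra!r} must be non-empty")

    @staticmethod
    def stage_order() -> tuple[str, ...]:
        """The single-parameter stages that follow the joint triple search."""
        return (
            "subsample_rate",
            "min_child_weight",
            "gamma",
            "alpha",
            "scale_pos_weight",
        )

    @classmethod
    def singleton(cls, params: HyperParams) -> "HyperParamGrid":
        """A grid with one candidate per list (tuning becomes a no-op)."""
        return cls(
            n_trees=(params.n_trees,),
            tree_depth=(params.tree_depth,),
            learning_rate=(params.learning_rate,),
            subsample_rate=(params.subsample_rate,),
            min_child_weight=(params.min_child_weight,),
            gamma=(params.gamma,),
            alpha=(params.alpha,),
            scale_pos_weight=(params.scale_pos_weight,),
        )

    def n_evaluations(self) -> int:
        """Sequential search size: |triple grid| + sum of later list lengths."""
        triple = (
            len(self.n_trees) * len(self.tree_depth) * len(self.learning_rate)
        )
        return triple + sum(len(getattr(self, s)) for s in self.stage_order())


@dataclass(frozen=True)
class RankedFeature:
    descriptor: FeatureDescriptor
    importance: float


class RankedFeatureList(list):
    """Feature descriptors with importance scores, non-increasing."""

    def top(self, m: int) -> list[FeatureDescriptor]:
        return [rf.descriptor for rf in self[:m]]


@dataclass
class FittedModel:
    booster: XGBClassifier
    descriptors: list[FeatureDescriptor]
    params: HyperParams


def _cv_score(
    X: np.ndarray,
    y: np.ndarray,
    params: HyperParams,
    folds: int,
    seed: int,
    criterion: str,
) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    scores = []
    for tr, va in skf.split(X, y):
        if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
            raise EngineError(
                "degenerate single-class CV fold; increase data or reduce folds"
            )
        clf = XGBClassifier(**params.to_xgb_kwargs(seed))
        clf.fit(X[tr], y[tr])
        prob = clf.predict_proba(X[va])[:, 1]
        if criterion == "ap":
            scores.append(average_precision_score(prob, y[va]))
        elif criterion == "logloss":
            eps = 1e-15
            p = np.clip(prob, eps, 1 - eps)
            scores.append(float(np.mean(y[va] * np.log(p) + (1 - y[va]) * np.log(1 - p))))
        else:
            raise EngineError(f"unknown tuning criterion {criterion!r}")
    return float(np.mean(scores))


def tune_sequential(
    train: CombinedFeatureMatrix,
    labels: np.ndarray,
    grid: HyperParamGrid | None = None,
    folds: int = 5,
    seed: int = 0,
    criterion: Literal["ap", "logloss"] = "ap",
) -> tuple[HyperParams, pd.DataFrame]:
    """Six-stage sequential hyperparameter search under stratified k-fold CV.

    Returns the winning :class:`HyperParams` and the tuning trace (stage,
    candidate, CV score) as a DataFrame.
    """
    grid = grid or HyperParamGrid()
    y = np.asarray(labels)
    X = train.X
    if min((y == 0).sum(), (y == 1).sum()) < folds:
        raise EngineError(f"need at least {folds} subjects per class for {folds}-fold CV")

    trace: list[dict] = []

    def evaluate(stage: str, candidate: HyperParams) -> float:
        score = _cv_score(X, y, candidate, folds, seed, criterion)
        trace.append({"stage": stage, "candidate": repr(candidate), "cv_score": score})
        return score

    def pick(scored: list[tuple[float, HyperParams]]) -> HyperParams:
        best = max(s for s, _ in scored)
        tied = [p for s, p in scored if s == best]
        return min(tied, key=HyperParams.complexity_key)

    # stage 1: joint triple
    scored = []
    for nt, td, lr in itertools.product(grid.n_trees, grid.tree_depth, grid.learning_rate):
        cand = HyperParams(n_trees=nt, tree_depth=td, learning_rate=lr)
        scored.append((evaluate("triple", cand), cand))
    current = pick(scored)

    # stages 2-6: one parameter at a time, earlier winners held fixed
    for stage in grid.stage_order():
        scored = []
        for value in getattr(grid, stage):
            cand = replace(current, **{stage: value})
            scored.append((evaluate(stage, cand), cand))
        current = pick(scored)

    return current, pd.DataFrame(trace)


def rank_features(
    train: CombinedFeatureMatrix,
    labels: np.ndarray,
    params: HyperParams,
    seed: int = 0,
    importance: str = "total_gain",
) -> RankedFeatureList:
    """Train one ensemble on all features; order by importance, descending.

    Importance defaults to total split gain.  Features the ensemble never
    splits on get importance 0.  Ties (including the all-zero case) keep the
    input column order, so the ranking is deterministic.
    """
    model = fit(train, labels, params, seed=seed)
    booster = model.booster.get_booster()
    raw = booster.get_score(importance_type=importance)
    scores = np.zeros(len(train.descriptors))
    for key, value in raw.items():
        scores[int(key.removeprefix("f"))] = value
    order = sorted(range(len(scores)), key=lambda j: (-scores[j], j))
    return RankedFeatureList(
        RankedFeature(train.descriptors[j], float(scores[j])) for j in order
    )


def fit(
    train: CombinedFeatureMatrix,
    labels: np.ndarray,
    params: HyperParams,
    feature_subset: Sequence[str] | None = None,
    seed: int = 0,
) -> FittedModel:
    """Train from scratch on (a column subset of) the design matrix."""
    design = train
    if feature_subset is not None:
        index = {d.name: j for j, d in enumerate(train.descriptors)}
        try:
            cols = [index[name] for name in feature_subset]
        except KeyError as exc:
            raise EngineError(f"unknown feature {exc.args[0]!r} in subset") from None
        design = train.subset_columns(cols)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise EngineError("training labels contain a single class")
    clf = XGBClassifier(**params.to_xgb_kwargs(seed))
    clf.fit(design.X, y)
    return FittedModel(booster=clf, descriptors=list(design.descriptors), params=params)


def predict(model: FittedModel, design: CombinedFeatureMatrix) -> np.ndarray:
    """Per-subject case probability; descriptor order must match training."""
    if [d.name for d in design.descriptors] != [d.name for d in model.descriptors]:
        raise EngineError(
            "prediction design descriptors do not match the training order"
        )
    return model.booster.predict_proba(design.X)[:, 1]
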