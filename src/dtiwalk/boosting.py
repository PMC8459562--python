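"""Boosting classifiers over edge features, with CV-driven tuning.

AdaBoost (scikit-learn, depth-1 decision stumps as weak learners) and
XGBoost are the two supported ensembles; both output interaction
likelihoods in [0, 1].  Hyperparameter search — exhaustive grid or seeded
uniform random sampling — scores every candidate by mean AUPR over
stratified folds of the *training* set only.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import average_precision_score
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from dtiwalk.features import EdgeFeatureSet

logger = logging.getLogger(__name__)

ALGORITHMS = ("adaboost", "xgboost")


@dataclass
class BoosterSpec:
    """Algorithm choice plus its hyperparameters."""

    algorithm: str = "xgboost"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )
        hp = self.hyperparameters
        for key in ("n_estimators", "max_depth"):
            if key in hp and hp[key] < 1:
                raise ValueError(f"{key} must be positive")
        if hp.get("learning_rate", 1.0) <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0 < hp.get("subsample", 1.0) <= 1):
            raise ValueError("subsample must lie in (0, 1]")

    def replace(self, **hyper) -> "BoosterSpec":
        merged = dict(self.hyperparameters)
        merged.update(hyper)
        return BoosterSpec(self.algorithm, merged, self.seed)


@dataclass
class TrainedModel:
    """A fitted predictor plus the BoosterSpec that produced it."""

    estimator: object
    spec: BoosterSpec
    n_features: int


def _make_estimator(spec: BoosterSpec):
    hp = spec.hyperparameters
    if spec.algorithm == "adaboost":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(
                max_depth=hp.get("max_depth", 1), random_state=spec.seed
            ),
            n_estimators=hp.get("n_estimators", 100),
            learning_rate=hp.get("learning_rate", 1.0),
            random_state=spec.seed,
        )
    return XGBClassifier(
        n_estimators=hp.get("n_estimators", 100),
        max_depth=hp.get("max_depth", 6),
        learning_rate=hp.get("learning_rate", 0.3),
        reg_lambda=hp.get("reg_lambda", 1.0),
        reg_alpha=hp.get("reg_alpha", 0.0),
        subsample=hp.get("subsample", 1.0),
        random_state=spec.seed,
        n_jobs=1,
        tree_method="exact",
        eval_metric="logloss",
    )


def train_booster(train: EdgeFeatureSet, spec: BoosterSpec) -> TrainedModel:
    """Fit the chosen booster; deterministic given seed (single thread)."""
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training labels must contain both classes")
    est = _make_estimator(spec)
    est.fit(train.X, train.labels)
    return TrainedModel(estimator=est, spec=spec, n_features=train.X.shape[1])


def predict_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Interaction likelihood in [0, 1] for every row of ``X``."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {X.shape[1] if X.ndim == 2 else X.shape} does not "
            f"match training width {model.n_features}"
        )
    if X.shape[0] == 0:
        return np.empty(0)
    return model.estimator.predict_proba(X)[:, 1]


def tune_hyperparameters(
    train: EdgeFeatureSet,
    space: dict[str, list],
    strategy: str = "grid",
    budget: int = 10,
    folds: int = 10,
    seed: int = 0,
    algorithm: str = "xgboost",
) -> tuple[BoosterSpec, float]:
    """Search the hyperparameter space by mean AUPR over stratified CV.

    ``grid`` enumerates the full Cartesian product of ``space``; ``randomized``
    draws ``budget`` distinct configurations uniformly with the seed.  Ties
    go to the first-encountered candidate.  Returns (best spec, its mean
    AUPR).
    """
    if not space:
        raise ValueError("hyperparameter space must be non-empty")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    names = sorted(space)
    grid = list(itertools.product(*(space[n] for n in names)))
    if strategy == "grid":
        candidates = grid
    elif strategy == "randomized":
        rng = np.random.default_rng(seed)
        take = min(budget, len(grid))
        idx = rng.choice(len(grid), size=take, replace=False)
        candidates = [grid[i] for i in idx]
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    best_spec, best_score = None, -np.inf
    for values in candidates:
        spec = BoosterSpec(algorithm, dict(zip(names, values)), seed)
        auprs = []
        for tr_idx, va_idx in skf.split(train.X, train.labels):
            sub = EdgeFeatureSet(
                pairs=[train.pairs[i] for i in tr_idx],
                X=train.X[tr_idx], labels=train.labels[tr_idx],
            )
            model = train_booster(sub, spec)
            scores = predict_scores(model, train.X[va_idx])
            auprs.append(average_precision_score(train.labels[va_idx], scores))
        mean_aupr = float(np.mean(auprs))
        logger.debug("candidate %s -> AUPR %.4f", spec.hyperparameters, mean_aupr)
        if mean_aupr > best_score:
            best_spec, best_score = spec, mean_aupr
    return best_spec, best_score
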