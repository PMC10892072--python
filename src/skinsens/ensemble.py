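"""Bagged gradient-boosted-tree classifier with majority voting.

One stage of the two-stage sensitization model is an ensemble of five
XGBoost classifiers. Each is trained on its own bootstrap subset (sampled
with replacement, 80% of the training set) after an exhaustive
hyperparameter grid search scored by 5-fold cross-validated balanced
accuracy; the stage's prediction is the majority vote of the five hard
labels. Bagging damps the variance a single tree ensemble shows on a
training set of ~100 substances, and balanced accuracy plus
``scale_pos_weight`` address the class imbalance.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

#: search grid for the hazard stage (sensitizer vs non-sensitizer); key order
#: fixes the enumeration (and therefore tie-breaking) order.
DEFAULT_HAZARD_GRID: dict[str, list] = {
    "learning_rate": [0.01, 0.1, 0.2],
    "n_estimators": [50, 100, 200, 300, 500],
    "max_depth": [3, 5, 7, 9],
    "subsample": [0.6, 0.8, 1.0],
    "scale_pos_weight": [0.5, 1.0],
}

#: search grid for the potency stage (strong 1A vs weak 1B); only the class
#: weighting differs, reflecting the flipped imbalance.
DEFAULT_POTENCY_GRID: dict[str, list] = {
    **{k: v for k, v in DEFAULT_HAZARD_GRID.items() if k != "scale_pos_weight"},
    "scale_pos_weight": [1.0, 2.0],
}

#: small single-point grid for quick runs and simulations
MINIMAL_GRID: dict[str, list] = {
    "learning_rate": [0.1],
    "n_estimators": [100],
    "max_depth": [3],
    "subsample": [0.8],
    "scale_pos_weight": [1.0],
}


@dataclass(frozen=True)
class StagePrediction:
    """Majority-vote outcome for one substance at one stage."""

    votes: tuple  # per-learner hard labels, in learner order
    label: object  # majority class
    vote_fraction: float  # fraction of positive votes


def enumerate_grid(grid: Mapping[str, Sequence]) -> list[dict]:
    """All grid points, in the order implied by the mapping's key order
    (first key slowest). Ties in CV score resolve to the earliest point."""
    keys = list(grid)
    if any(len(grid[k]) == 0 for k in keys):
        raise ValidationError("every grid dimension must be non-empty")
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def make_subsets(
    train_ids: Sequence, k: int = 5, fraction: float = 0.8, seed: int = 0
) -> list[list]:
    """Draw ``k`` bootstrap subsets of round(fraction*n) ids with replacement.

    Draws are keyed to the sorted id list, so the result depends on the id
    multiset only, not on row order. Each subset uses an independently
    spawned generator derived from ``seed``.
    """
    if not train_ids:
        raise ValidationError("training set is empty")
    if not 0 < fraction <= 1:
        raise ValidationError("subset fraction must be in (0, 1]")
    ids = sorted(train_ids, key=str)
    n = len(ids)
    size = math.floor(fraction * n + 0.5)  # round half up
    children = np.random.SeedSequence(seed).spawn(k)
    subsets = []
    for child in children:
        rng = np.random.default_rng(child)
        draws = rng.integers(0, n, size=size)
        subsets.append([ids[i] for i in draws])
    return subsets


def _base_learner(params: Mapping, seed: int) -> XGBClassifier:
    return XGBClassifier(
        **params,
        tree_method="hist",
        n_jobs=1,
        random_state=int(seed),
        eval_metric="logloss",
        verbosity=0,
    )


def tune_base_learner(
    X: pd.DataFrame,
    y01: np.ndarray,
    grid: Mapping[str, Sequence],
    folds: int = 5,
    seed: int = 0,
) -> tuple[XGBClassifier, dict, float]:
    """Exhaustive grid search maximizing stratified-CV balanced accuracy.

    Ties break to the first grid point in enumeration order. The returned
    learner is refitted on the whole subset with the chosen point. When the
    minority class has fewer members than ``folds`` the fold count drops to
    that class count (with a warning); with a singleton minority class CV is
    impossible and the first grid point is taken directly.
    """
    points = enumerate_grid(grid)
    classes, counts = np.unique(y01, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("both classes must be present in the training subset")
    min_class = int(counts.min())
    rng = np.random.default_rng(seed)
    fit_seed = int(rng.integers(2**31))

    if min_class < 2:
        logger.warning("minority class has 1 member; skipping CV, using first grid point")
        chosen, score = points[0], float("nan")
    else:
        n_splits = min(folds, min_class)
        if n_splits < folds:
            logger.warning("reducing CV folds from %d to %d (minority class size)", folds, n_splits)
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        splits = list(skf.split(np.zeros(len(y01)), y01))
        best_idx, best_score = 0, -np.inf
        for i, point in enumerate(points):
            fold_scores = []
            for tr, va in splits:
                clf = _base_learner(point, fit_seed)
                clf.fit(X.iloc[tr], y01[tr])
                fold_scores.append(balanced_accuracy_score(y01[va], clf.predict(X.iloc[va])))
            mean_score = float(np.mean(fold_scores))
            if mean_score > best_score:  # strict: first max wins ties
                best_idx, best_score = i, mean_score
        chosen, score = points[best_idx], best_score

    final = _base_learner(chosen, fit_seed)
    final.fit(X, y01)
    return final, chosen, score


class BaggedXGBClassifier(BaseEstimator, ClassifierMixin):
    """Bagging ensemble of grid-tuned XGBoost classifiers with majority vote.

    Parameters
    ----------
    param_grid : mapping of hyperparameter name -> candidate values
        Search space per base learner (default: the hazard-stage grid).
    n_learners : int, default 5
        Number of bootstrap subsets / base learners. Odd counts keep the
        vote decisive.
    subset_fraction : float, default 0.8
        Bootstrap subset size as a fraction of the training set
        (round-half-up, sampled with replacement).
    cv : int, default 5
        Cross-validation folds for the per-subset grid search.
    pos_label : object, optional
        Which class is "positive" (receives ``scale_pos_weight``); default is
        the lexicographically larger of the two classes.
    vote_threshold : float, default 0.6
        Minimum positive vote fraction for a positive call (3 of 5).
    random_state : int, default 0
        Master seed; subset draws and per-learner searches derive from it.

    Attributes
    ----------
    classes_ : ndarray of the two class labels.
    learners_ : list of fitted XGBoost classifiers (length ``n_learners``).
    chosen_params_ : list of the grid points the per-subset searches picked.
    cv_scores_ : per-learner mean CV balanced accuracy of the chosen point.
    subset_ids_ : per-learner multiset (list) of training ids drawn.
    feature_names_ : column names seen during fit.
    """

    def __init__(
        self,
        param_grid: Mapping[str, Sequence] | None = None,
        n_learners: int = 5,
        subset_fraction: float = 0.8,
        cv: int = 5,
        pos_label=None,
        vote_threshold: float = 0.6,
        random_state: int = 0,
    ):
        self.param_grid = param_grid
        self.n_learners = n_learners
        self.subset_fraction = subset_fraction
        self.cv = cv
        self.pos_label = pos_label
        self.vote_threshold = vote_threshold
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------
    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        return pd.DataFrame(np.asarray(X, dtype=float))

    def _check_features(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.feature_names_ if c not in X.columns]
        if missing:
            raise ValidationError(f"missing feature(s) at predict time: {missing}")
        return X[self.feature_names_]

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y, ids: Sequence | None = None) -> "BaggedXGBClassifier":
        X = self._as_frame(X)
        y = np.asarray(y)
        if X.isna().to_numpy().any():
            raise ValidationError("training features contain missing values; "
                                  "drop incomplete rows first")
        if len(X) != len(y):
            raise ValidationError("X and y length mismatch")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValidationError(f"need exactly 2 classes, got {list(classes)}")
        self.classes_ = classes
        pos = self.pos_label if self.pos_label is not None else classes[1]
        if pos not in classes:
            raise ValidationError(f"pos_label {pos!r} not among classes {list(classes)}")
        self.positive_class_ = pos
        self.negative_class_ = classes[0] if classes[1] == pos else classes[1]

        if ids is None:
            ids = list(X.index) if isinstance(X, pd.DataFrame) else list(range(len(y)))
        ids = list(ids)
        if len(set(ids)) != len(ids):
            raise ValidationError("training ids must be unique")
        id_to_row = {i: r for r, i in enumerate(ids)}

        grid = dict(self.param_grid) if self.param_grid is not None else dict(DEFAULT_HAZARD_GRID)
        subsets = make_subsets(ids, self.n_learners, self.subset_fraction,
                               seed=self.random_state)
        tune_seeds = np.random.SeedSequence([self.random_state, 1]).spawn(self.n_learners)

        y01 = (y == pos).astype(int)
        self.learners_, self.chosen_params_, self.cv_scores_ = [], [], []
        self.subset_ids_ = subsets
        self.feature_names_ = list(X.columns)
        self.n_features_in_ = len(self.feature_names_)
        for subset, seed_seq in zip(subsets, tune_seeds):
            rows = [id_to_row[i] for i in subset]
            sub_seed = int(np.random.default_rng(seed_seq).integers(2**31))
            learner, params, score = tune_base_learner(
                X.iloc[rows], y01[rows], grid, folds=self.cv, seed=sub_seed
            )
            self.learners_.append(learner)
            self.chosen_params_.append(params)
            self.cv_scores_.append(score)
        return self

    def _votes(self, X: pd.DataFrame) -> np.ndarray:
        X = self._check_features(self._as_frame(X))
        return np.column_stack([lr.predict(X) for lr in self.learners_])

    def vote_fraction(self, X) -> np.ndarray:
        """Fraction of base learners voting for the positive class, per row."""
        return self._votes(X).mean(axis=1)

    def predict(self, X) -> np.ndarray:
        frac = self.vote_fraction(X)
        return np.where(frac >= self.vote_threshold,
                        self.positive_class_, self.negative_class_)

    def predict_stage(self, X) -> list[StagePrediction]:
        """Full voting detail per row (per-learner labels + vote fraction)."""
        votes01 = self._votes(X)
        out = []
        for row in votes01:
            frac = float(row.mean())
            label = self.positive_class_ if frac >= self.vote_threshold else self.negative_class_
            labels = tuple(self.positive_class_ if v else self.negative_class_ for v in row)
            out.append(StagePrediction(labels, label, frac))
        return out

    def score(self, X, y) -> float:
        return float(balanced_accuracy_score(np.asarray(y), self.predict(X)))


def fit_bagged(X, y, grid=None, seed: int = 0, **kwargs) -> BaggedXGBClassifier:
    """Functional wrapper: fit a :class:`BaggedXGBClassifier`."""
    return BaggedXGBClassifier(param_grid=grid, random_state=seed, **kwargs).fit(X, y)


def predict_vote(model: BaggedXGBClassifier, features) -> StagePrediction:
    """Majority-vote prediction for a single feature row."""
    row = features if isinstance(features, pd.DataFrame) else pd.DataFrame([features])
    return model.predict_stage(row)[0]
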