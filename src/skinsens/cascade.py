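"""Two-stage NC/1B/1A classifier composed of two bagged stage models.

Stage 1 separates sensitizers from non-sensitizers on the full training
set; stage 2 separates strong (1A) from weak (1B) sensitizers and is
trained only on the true sensitizers (not on stage-1 positives), so it can
also be evaluated independently on every true sensitizer in a test set.

Two prediction protocols are supported:

* ``cascaded`` — stage 2 runs only when stage 1 calls "sensitizer"; a
  stage-1 negative is final (NC). This is how the deployed model labels an
  unknown substance.
* ``independent`` — stage 2 runs on every substance regardless of stage 1;
  used to score the potency model on all true sensitizers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .data_model import derive_labels
from .ensemble import (
    DEFAULT_HAZARD_GRID,
    DEFAULT_POTENCY_GRID,
    BaggedXGBClassifier,
    StagePrediction,
)
from .exceptions import ValidationError

CLASS_ORDER = ("NC", "1B", "1A")  # severity order: NC < 1B < 1A


@dataclass
class CascadeResult:
    """Per-substance outcome of the two-stage classifier."""

    id: object
    final_class: str  # "NC" | "1B" | "1A"
    stage1: StagePrediction
    stage2: StagePrediction | None  # absent for NC in cascaded mode


def labels_from_categories(categories) -> pd.DataFrame:
    """Hazard and potency stage labels for a vector of categories 1-6."""
    recs = [derive_labels(int(c)) for c in categories]
    return pd.DataFrame(
        {"hazard": [r.hazard for r in recs], "potency": [r.potency for r in recs]}
    )


def final_class_from_category(category: int) -> str:
    """Ground-truth 3-class label (NC/1B/1A) for a potency category 1-6."""
    lab = derive_labels(int(category))
    return "NC" if lab.hazard == "non_sensitizer" else lab.potency


class TwoStageSensitizerClassifier(BaseEstimator, ClassifierMixin):
    """Cascade of two :class:`BaggedXGBClassifier` stages.

    Parameters
    ----------
    stage1_grid, stage2_grid : hyperparameter grids per stage (defaults:
        the hazard and potency grids).
    stage1_features, stage2_features : optional feature-name lists; each
        stage may use its own subset of the columns of ``X``. ``None`` means
        all columns.
    n_learners, subset_fraction, cv : passed through to both stages.
    random_state : master seed (stage seeds derive from it).

    Attributes
    ----------
    stage1_ : fitted hazard model (positive class "sensitizer").
    stage2_ : fitted potency model (positive class "1A").
    classes_ : ("NC", "1B", "1A").
    """

    def __init__(
        self,
        stage1_grid=None,
        stage2_grid=None,
        stage1_features=None,
        stage2_features=None,
        n_learners: int = 5,
        subset_fraction: float = 0.8,
        cv: int = 5,
        random_state: int = 0,
    ):
        self.stage1_grid = stage1_grid
        self.stage2_grid = stage2_grid
        self.stage1_features = stage1_features
        self.stage2_features = stage2_features
        self.n_learners = n_learners
        self.subset_fraction = subset_fraction
        self.cv = cv
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y, ids=None) -> "TwoStageSensitizerClassifier":
        """Fit both stages from potency categories ``y`` (integers 1-6).

        Stage 2 is trained on the records whose *true* label is sensitizer.
        """
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        labels = labels_from_categories(y)
        if ids is None:
            ids = list(X.index)
        ids = list(ids)

        sens_mask = (labels["hazard"] == "sensitizer").to_numpy()
        n_sens = int(sens_mask.sum())
        if n_sens == 0:
            raise ValidationError("no sensitizers in the training set; cannot fit stage 2")
        pot = labels.loc[sens_mask, "potency"]
        if (pot == "1A").sum() < 2 or (pot == "1B").sum() < 2:
            raise ValidationError(
                "need at least 2 training sensitizers of each potency class (1A/1B)"
            )
        if n_sens < 10:
            import logging

            logging.getLogger(__name__).warning(
                "only %d sensitizers in training; stage 2 will be weak", n_sens
            )

        f1 = list(self.stage1_features) if self.stage1_features is not None else list(X.columns)
        f2 = list(self.stage2_features) if self.stage2_features is not None else list(X.columns)
        s1_seed, s2_seed = (
            int(np.random.default_rng(s).integers(2**31))
            for s in np.random.SeedSequence(self.random_state).spawn(2)
        )
        self.stage1_ = BaggedXGBClassifier(
            param_grid=self.stage1_grid or DEFAULT_HAZARD_GRID,
            n_learners=self.n_learners,
            subset_fraction=self.subset_fraction,
            cv=self.cv,
            pos_label="sensitizer",
            random_state=s1_seed,
        ).fit(X[f1], labels["hazard"].to_numpy(), ids=ids)
        self.stage2_ = BaggedXGBClassifier(
            param_grid=self.stage2_grid or DEFAULT_POTENCY_GRID,
            n_learners=self.n_learners,
            subset_fraction=self.subset_fraction,
            cv=self.cv,
            pos_label="1A",
            random_state=s2_seed,
        ).fit(
            X.loc[sens_mask, f2],
            labels.loc[sens_mask, "potency"].to_numpy(),
            ids=[i for i, m in zip(ids, sens_mask) if m],
        )
        self.classes_ = np.asarray(CLASS_ORDER)
        return self

    def predict_detail(self, X: pd.DataFrame, mode: str = "cascaded") -> list[CascadeResult]:
        """Per-substance stage-wise votes and the final NC/1B/1A call."""
        if mode not in ("cascaded", "independent"):
            raise ValidationError(f"unknown prediction mode {mode!r}")
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        s1 = self.stage1_.predict_stage(X)
        s2 = self.stage2_.predict_stage(X)
        out = []
        for rid, p1, p2 in zip(X.index, s1, s2):
            if p1.label == "non_sensitizer":
                out.append(CascadeResult(rid, "NC", p1, p2 if mode == "independent" else None))
            else:
                out.append(CascadeResult(rid, p2.label, p1, p2))
        return out

    def predict(self, X, mode: str = "cascaded") -> np.ndarray:
        return np.asarray([r.final_class for r in self.predict_detail(X, mode)])

    def score(self, X, y) -> float:
        """Overall 3-class accuracy against potency categories 1-6."""
        truth = np.asarray([final_class_from_category(c) for c in np.asarray(y)])
        return float(np.mean(self.predict(X) == truth))


def fit_cascade(X, y, seed: int = 0, **kwargs) -> TwoStageSensitizerClassifier:
    """Functional wrapper: fit the two-stage classifier."""
    return TwoStageSensitizerClassifier(random_state=seed, **kwargs).fit(X, y)


def predictions_frame(results: list[CascadeResult]) -> pd.DataFrame:
    """Prediction output table: id, final class, stage vote fractions."""
    return pd.DataFrame(
        {
            "id": [r.id for r in results],
            "final_class": [r.final_class for r in results],
            "stage1_vote_fraction": [r.stage1.vote_fraction for r in results],
            "stage2_vote_fraction": [
                r.stage2.vote_fraction if r.stage2 is not None else np.nan
                for r in results
            ],
        }
    )
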