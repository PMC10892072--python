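"""Per-substance additive feature attributions averaged over the ensemble.

Each base learner yields exact Tree SHAP attributions on the margin
(log-odds) scale, where additivity holds exactly: for every substance,
base value + sum of per-feature attributions = that learner's raw margin.
The ensemble-level explanation is the unweighted mean of the five
learners' attributions. Because the final call is a majority vote of hard
labels — not a mean of margins — the sign of the summed average SHAP can
occasionally disagree with the voted label; such substances are flagged,
not treated as errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb

from .ensemble import BaggedXGBClassifier, StagePrediction
from .exceptions import ValidationError


@dataclass
class AttributionSet:
    """SHAP-style attributions for a test matrix under one bagged model.

    ``per_learner`` is (k, n, p) feature attributions; ``base_values`` is
    (k, n) expected margins; ``averaged`` is the (n, p) mean over learners;
    ``margins`` is the (k, n) raw margin each learner assigns.
    """

    feature_names: list[str]
    ids: list
    per_learner: np.ndarray
    base_values: np.ndarray
    averaged: np.ndarray
    margins: np.ndarray

    def averaged_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.averaged, index=self.ids, columns=self.feature_names)


def attribute(model: BaggedXGBClassifier, X: pd.DataFrame) -> AttributionSet:
    """Exact per-learner tree-path attributions plus their ensemble mean."""
    if not hasattr(model, "learners_"):
        raise ValidationError("model is not fitted")
    missing = [c for c in model.feature_names_ if c not in X.columns]
    if missing:
        raise ValidationError(f"missing feature(s): {missing}")
    X = X[model.feature_names_]
    k, p = len(model.learners_), len(model.feature_names_)
    if len(X) == 0:
        empty = np.zeros((k, 0, p))
        return AttributionSet(list(model.feature_names_), [], empty,
                              np.zeros((k, 0)), np.zeros((0, p)), np.zeros((k, 0)))
    dmat = xgb.DMatrix(X, feature_names=model.feature_names_)
    contribs, bases, margins = [], [], []
    for lr in model.learners_:
        booster = lr.get_booster()
        c = booster.predict(dmat, pred_contribs=True)  # (n, p+1), last col = bias
        contribs.append(c[:, :-1])
        bases.append(c[:, -1])
        margins.append(booster.predict(dmat, output_margin=True))
    per_learner = np.asarray(contribs)
    return AttributionSet(
        feature_names=list(model.feature_names_),
        ids=list(X.index),
        per_learner=per_learner,
        base_values=np.asarray(bases),
        averaged=per_learner.mean(axis=0),
        margins=np.asarray(margins),
    )


def summary_ranking(attribs: AttributionSet, by_abs: bool = True) -> list[str]:
    """Features ordered by descending mean |averaged attribution|.

    ``by_abs=False`` ranks on the signed mean instead. Ties break by
    feature name.
    """
    if attribs.averaged.shape[0] == 0:
        raise ValidationError("no substances to summarize")
    vals = np.abs(attribs.averaged).mean(axis=0) if by_abs else attribs.averaged.mean(axis=0)
    pairs = sorted(zip(attribs.feature_names, vals), key=lambda t: (-t[1], t[0]))
    return [f for f, _ in pairs]


def vote_shap_concordance(
    attribs: AttributionSet, predictions: list[StagePrediction], positive=None
) -> pd.DataFrame:
    """Flag substances whose summed average SHAP disagrees with the vote.

    The implied margin sign (mean base value + summed averaged attributions
    > 0 means "positive") is compared with the majority-vote label. A
    discordance is an expected property of vote aggregation, not a defect.
    """
    if len(predictions) != len(attribs.ids):
        raise ValidationError("predictions and attributions are misaligned")
    rows = []
    for i, (rid, pred) in enumerate(zip(attribs.ids, predictions)):
        implied = attribs.base_values[:, i].mean() + attribs.averaged[i].sum()
        shap_positive = implied > 0
        vote_positive = (
            pred.label == positive if positive is not None else pred.vote_fraction >= 0.6
        )
        rows.append(
            {
                "id": rid,
                "implied_margin": implied,
                "vote_fraction": pred.vote_fraction,
                "concordant": bool(shap_positive == vote_positive),
            }
        )
    return pd.DataFrame(rows)


def attribution_csv(attribs: AttributionSet) -> pd.DataFrame:
    """Long-format export: id x feature averaged attribution."""
    df = attribs.averaged_frame()
    out = df.reset_index(names="id").melt(id_vars="id", var_name="feature",
                                          value_name="mean_shap")
    return out
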