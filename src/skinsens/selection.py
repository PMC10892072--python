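"""Feature selection by gain importance averaged over the bagged learners.

The selection protocol: rank features by the arithmetic mean of per-learner
gain (loss-reduction) importance; compare candidate models built from the
full feature set and the tie-inclusive top-k sets; optionally swap the
least-important in vitro assay for the best feature left outside the model
(an assay is expensive to run, a computed descriptor is free). The winner
is the candidate with the highest test balanced accuracy, ties going to
the smaller feature set and then to the assay-substituted variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ensemble import BaggedXGBClassifier
from .exceptions import ValidationError


def average_importance(model: BaggedXGBClassifier) -> pd.DataFrame:
    """Mean gain importance per feature across the five base learners.

    A feature never used by a learner contributes 0 for that learner.
    Returns a table (feature, imp_0..imp_{k-1}, mean, rank) sorted by
    descending mean; tied means share the same (min) rank.
    """
    if not hasattr(model, "learners_"):
        raise ValidationError("model is not fitted")
    feats = model.feature_names_
    per_learner = []
    for lr in model.learners_:
        score = lr.get_booster().get_score(importance_type="gain")
        per_learner.append([float(score.get(f, 0.0)) for f in feats])
    arr = np.asarray(per_learner)  # (k, p)
    table = pd.DataFrame(
        arr.T, index=pd.Index(feats, name="feature"),
        columns=[f"imp_{i}" for i in range(len(model.learners_))],
    )
    table["mean"] = arr.mean(axis=0)
    table = table.sort_values("mean", ascending=False, kind="stable")
    table["rank"] = table["mean"].rank(method="min", ascending=False).astype(int)
    return table


def top_k(table: pd.DataFrame, k: int) -> list[str]:
    """The k highest-mean-importance features, expanding ties at the cutoff.

    If the k-th value is shared, every feature tied with it is included, so
    the list may exceed k (e.g. a 15th-place tie yields 16 features).
    """
    if k <= 0:
        raise ValidationError("k must be positive")
    if k > len(table):
        raise ValidationError(f"k={k} exceeds feature count {len(table)}")
    means = table["mean"].to_numpy()
    order = np.argsort(-means, kind="stable")
    cutoff = means[order[k - 1]]
    return [table.index[i] for i in order if means[i] >= cutoff]


def substitute_assay(
    selected: Sequence[str], table: pd.DataFrame, assay_features: set[str]
) -> list[str]:
    """Swap the least-important selected assay for the best excluded feature.

    Removes the lowest-mean-importance assay feature present in ``selected``
    and appends the highest-mean-importance feature not yet selected; the
    list length is preserved.
    """
    selected = list(selected)
    means = table["mean"]
    assays_in = [f for f in selected if f in assay_features]
    if not assays_in:
        raise ValidationError("no assay feature present in the selected list")
    pool = [f for f in table.index if f not in set(selected)]
    if not pool:
        raise ValidationError("no excluded feature available as a substitute")
    worst_assay = min(assays_in, key=lambda f: (means[f], f))
    best_outside = max(pool, key=lambda f: (means[f], -table.index.get_loc(f)))
    out = [f for f in selected if f != worst_assay]
    out.append(best_outside)
    return out


@dataclass
class CandidateResult:
    name: str
    features: list[str]
    balanced_accuracy: float
    substituted: bool = False


def compare_feature_sets(
    X_train: pd.DataFrame,
    y_train,
    X_test: pd.DataFrame,
    y_test,
    candidates: Mapping[str, Sequence[str]],
    grid=None,
    seed: int = 0,
    substituted_names: set[str] | None = None,
    **fit_kwargs,
) -> tuple[CandidateResult, list[CandidateResult]]:
    """Refit the bagged pipeline per candidate feature set and pick a winner.

    Every candidate is trained on the identical training rows and seed and
    scored by balanced accuracy on the held-out test rows (note: selecting
    on the test set risks optimistic bias; the report keeps all candidate
    scores so that can be audited). Selection: highest balanced accuracy,
    ties to fewer features, then to an assay-substituted candidate.
    """
    if len(candidates) < 1:
        raise ValidationError("need at least one candidate feature set")
    substituted_names = substituted_names or set()
    results = []
    for name, feats in candidates.items():
        feats = list(feats)
        model = BaggedXGBClassifier(param_grid=grid, random_state=seed,
                                    **fit_kwargs).fit(X_train[feats], y_train)
        ba = model.score(X_test[feats], y_test)
        results.append(CandidateResult(name, feats, ba, name in substituted_names))
    best = max(
        results,
        key=lambda r: (r.balanced_accuracy, -len(r.features), r.substituted),
    )
    return best, results
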