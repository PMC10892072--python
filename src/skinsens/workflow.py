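"""End-to-end study pipeline: table -> features -> split -> cascade -> report.

Mirrors the full modelling protocol: encode assays (EC1.5 capped,
SENS-IS binarized), remove incomplete rows, add the scalar embedding
feature, stratified 8:2 split by potency category, prune correlated
descriptors and standardize on the training rows only, fit the two-stage
bagged classifier, and score the held-out test set (stage 1 on all test
substances, stage 2 independently on the true test sensitizers, plus the
cascaded 3-class potency table).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cascade import (
    TwoStageSensitizerClassifier,
    final_class_from_category,
    predictions_frame,
)
from .data_model import Dataset
from .embedding import EmbeddingProvider, TrigramHashEmbedder, smiles_scalar_feature
from .ensemble import DEFAULT_HAZARD_GRID, DEFAULT_POTENCY_GRID
from .evaluate import (
    ConfusionMatrix2,
    ConfusionMatrix3,
    DomainRanges,
    auc_variants,
    metrics_from_confusion,
    potency_table,
)
from .exceptions import ValidationError
from .preprocess import (
    ASSAY_FEATURES,
    EMBEDDING_FEATURE,
    CorrelationPruner,
    SplitResult,
    apply_standardizer,
    drop_incomplete,
    feature_frame,
    fit_standardizer,
    stratified_split,
)


@dataclass
class StudyResult:
    """Everything a study run produces, for reporting and reuse."""

    model: TwoStageSensitizerClassifier
    split: SplitResult
    features_train: pd.DataFrame
    features_test: pd.DataFrame
    y_train: pd.Series
    y_test: pd.Series
    pruned: dict
    stage1_metrics: dict
    stage2_metrics: dict
    potency_report: dict
    predictions: pd.DataFrame
    domain: DomainRanges
    scaler: object = None
    config: dict = field(default_factory=dict)


def build_features(
    dataset: Dataset, provider: EmbeddingProvider | None = None
) -> pd.DataFrame:
    """Assay + descriptor + embedding feature table, indexed by substance id.

    If the records already carry a ``roberta_embedding_mean`` column (the
    synthetic generator emits one) it is used as-is; otherwise the scalar is
    computed from each SMILES with the given embedding provider (default:
    the offline trigram-hash backend).
    """
    df = feature_frame(dataset)
    if EMBEDDING_FEATURE not in df.columns:
        provider = provider or TrigramHashEmbedder()
        df[EMBEDDING_FEATURE] = [
            smiles_scalar_feature(r.smiles, provider) for r in dataset
        ]
    return df


def run_study(
    dataset: Dataset,
    seed: int = 0,
    stage1_grid=None,
    stage2_grid=None,
    test_fraction: float = 0.2,
    prune_threshold: float = 0.75,
    n_learners: int = 5,
    cv: int = 5,
    provider: EmbeddingProvider | None = None,
) -> StudyResult:
    """Run the full two-stage modelling study on a labelled substance table."""
    complete = drop_incomplete(dataset, ASSAY_FEATURES)
    if len(complete) < 20:
        raise ValidationError(
            f"only {len(complete)} complete records; too few to train and test"
        )
    features = build_features(complete, provider)
    y = pd.Series(
        [r.potency_category for r in complete], index=features.index, name="potency_category"
    )
    if y.isna().any():
        raise ValidationError("every record needs a potency category for a study run")

    split = stratified_split(complete, test_fraction=test_fraction, seed=seed)
    X_train, X_test = features.loc[split.train_ids], features.loc[split.test_ids]
    y_train, y_test = y.loc[split.train_ids], y.loc[split.test_ids]

    # redundancy-prune descriptors only; assays and the embedding are kept
    descriptor_cols = [
        c for c in features.columns if c not in ASSAY_FEATURES and c != EMBEDDING_FEATURE
    ]
    pruner = CorrelationPruner(threshold=prune_threshold)
    kept_desc = list(descriptor_cols)
    dropped: dict = {}
    if len(descriptor_cols) >= 2:
        pruner.fit(X_train[descriptor_cols])
        kept_desc, dropped = pruner.kept_, pruner.dropped_

    model_cols = list(ASSAY_FEATURES) + kept_desc + [EMBEDDING_FEATURE]
    scaler = fit_standardizer(X_train, kept_desc + [EMBEDDING_FEATURE])
    X_train_s = apply_standardizer(scaler, X_train[model_cols])
    X_test_s = apply_standardizer(scaler, X_test[model_cols])

    model = TwoStageSensitizerClassifier(
        stage1_grid=stage1_grid or DEFAULT_HAZARD_GRID,
        stage2_grid=stage2_grid or DEFAULT_POTENCY_GRID,
        n_learners=n_learners,
        cv=cv,
        random_state=seed,
    ).fit(X_train_s, y_train.to_numpy(), ids=list(X_train_s.index))

    # --- evaluation ------------------------------------------------------
    truth3 = [final_class_from_category(c) for c in y_test]
    results = model.predict_detail(X_test_s, mode="cascaded")
    pred3 = [r.final_class for r in results]

    s1_true = [1 if t != "NC" else 0 for t in truth3]
    s1_pred = model.stage1_.predict_stage(X_test_s)
    s1_hard = [1 if p.label == "sensitizer" else 0 for p in s1_pred]
    cm1 = ConfusionMatrix2.from_pairs(s1_true, s1_hard, positive=1)
    stage1_metrics = metrics_from_confusion(cm1).as_dict()
    if len(set(s1_true)) == 2:
        auc_h, auc_s = auc_variants(
            s1_true, [p.vote_fraction for p in s1_pred], hard_labels=s1_hard
        )
        stage1_metrics.update(auc_hard=auc_h, auc_score=auc_s)

    sens_mask = [t != "NC" for t in truth3]
    stage2_metrics: dict = {}
    if any(sens_mask):
        s2_true = [1 if t == "1A" else 0 for t, m in zip(truth3, sens_mask) if m]
        s2_pred = model.stage2_.predict_stage(X_test_s.loc[sens_mask])
        s2_hard = [1 if p.label == "1A" else 0 for p in s2_pred]
        if len(set(s2_true)) == 2:
            cm2 = ConfusionMatrix2.from_pairs(s2_true, s2_hard, positive=1)
            stage2_metrics = metrics_from_confusion(cm2).as_dict()
            auc_h, auc_s = auc_variants(
                s2_true, [p.vote_fraction for p in s2_pred], hard_labels=s2_hard
            )
            stage2_metrics.update(auc_hard=auc_h, auc_score=auc_s)

    potency_report: dict = {}
    if all(c in truth3 for c in ("NC", "1B", "1A")):
        cm3 = ConfusionMatrix3.from_pairs(truth3, pred3)
        potency_report = potency_table(cm3)

    return StudyResult(
        model=model,
        split=split,
        features_train=X_train_s,
        features_test=X_test_s,
        y_train=y_train,
        y_test=y_test,
        pruned={"kept": kept_desc, "dropped": dropped},
        stage1_metrics=stage1_metrics,
        stage2_metrics=stage2_metrics,
        potency_report=potency_report,
        predictions=predictions_frame(results),
        domain=DomainRanges.fit(X_train[model_cols]),
        scaler=scaler,
        config={
            "seed": seed,
            "test_fraction": test_fraction,
            "prune_threshold": prune_threshold,
            "n_learners": n_learners,
            "cv": cv,
        },
    )
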