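"""Assay encoding, censoring, correlation pruning, scaling and splitting.

The feature table fed to the classifiers has three blocks:

* five assay features — C-peptide and K-peptide depletion (%, continuous),
  KeratinoSens EC1.5 (continuous, right-censored at 2000), h-CLAT (0/1) and
  SENS-IS_cat (0/1, positive for any sensitizer call from extreme to weak);
* an open block of named physicochemical descriptors, redundancy-pruned at
  |Pearson r| >= 0.75 and standardized to mean 0 / variance 1;
* the scalar SMILES-embedding feature ``roberta_embedding_mean``.

Pruning applies to descriptors only: assay readouts and the embedding scalar
are domain-chosen inputs, not a redundant descriptor pool.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import Dataset, SubstanceRecord
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

EC15_CAP = 2000.0

ASSAY_FEATURES = ["C-peptide", "K-peptide", "EC1.5", "h-CLAT", "SENS-IS_cat"]
EMBEDDING_FEATURE = "roberta_embedding_mean"

_SENSIS_POSITIVE = {"extreme", "strong", "moderate", "weak"}


def cap_ec15(value: float | None) -> float | None:
    """Right-censor an EC1.5 readout at 2000 (missing passes through)."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return value
    if not value > 0:
        raise ValidationError(f"EC1.5 must be positive, got {value}")
    return min(float(value), EC15_CAP)


def encode_assays(record: SubstanceRecord) -> dict[str, float | None]:
    """Encode one substance's assay readouts as named model features.

    Depletions and EC1.5 stay continuous (EC1.5 capped); h-CLAT is already
    binary; the 5-level SENS-IS call is binarized (any sensitizer level is
    positive). Missing readouts propagate as ``None``.
    """
    sensis: float | None
    if record.sensis_class is None:
        sensis = None
    else:
        sensis = float(record.sensis_class in _SENSIS_POSITIVE)
    return {
        "C-peptide": record.dpra_c_depletion,
        "K-peptide": record.dpra_k_depletion,
        "EC1.5": cap_ec15(record.keratinosens_ec15),
        "h-CLAT": None if record.hclat_positive is None else float(record.hclat_positive),
        "SENS-IS_cat": sensis,
    }


def feature_frame(dataset: Dataset) -> pd.DataFrame:
    """Assay features + descriptors (+ embedding column if generated) per substance.

    Index is the substance id. The embedding scalar is included only when the
    records carry it as a descriptor named ``roberta_embedding_mean``; otherwise
    it is appended separately by the embedding module.
    """
    rows = []
    for r in dataset:
        row = encode_assays(r)
        for f in dataset.feature_names:
            row[f] = r.descriptors.get(f)
        rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index(dataset.ids(), name="id"), dtype=float)
    return df


def drop_incomplete(dataset: Dataset, required_features: Sequence[str]) -> Dataset:
    """Remove records missing any required feature (order preserved)."""
    if not required_features:
        return Dataset(list(dataset.records), list(dataset.feature_names))
    kept = []
    for r in dataset:
        feats = encode_assays(r)
        feats.update(r.descriptors)
        if all(
            feats.get(f) is not None and not math.isnan(feats[f])
            for f in required_features
        ):
            kept.append(r)
    if not kept:
        logger.warning("drop_incomplete removed every record")
    return Dataset(kept, list(dataset.feature_names))


# ---------------------------------------------------------------------------
# correlation pruning


@dataclass
class PruneConfig:
    threshold: float = 0.75
    representative_rule: str = "first_in_column_order"

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValidationError("prune threshold must be in (0, 1]")
        if self.representative_rule not in ("first_in_column_order", "highest_variance"):
            raise ValidationError(f"unknown rule {self.representative_rule!r}")


def prune_correlated(
    matrix: pd.DataFrame, config: PruneConfig | None = None
) -> tuple[list[str], dict[str, str | None]]:
    """Greedy redundancy filter at |Pearson r| >= threshold.

    Scans features (in column order, or by descending variance under the
    ``highest_variance`` rule), keeps a feature iff it is below-threshold
    correlated with every feature kept so far, and maps each dropped feature
    to the kept representative that triggered the drop. Zero-variance columns
    are dropped with representative ``None`` (their correlation is undefined).

    Returns ``(kept, dropped)`` where dropped maps name -> representative.
    """
    config = config or PruneConfig()
    if len(matrix) < 2:
        raise ValidationError("pruning needs at least 2 rows")
    X = matrix.to_numpy(dtype=float)
    names = list(matrix.columns)
    order = range(len(names))
    if config.representative_rule == "highest_variance":
        variances = X.var(axis=0)
        order = sorted(order, key=lambda j: (-variances[j], j))

    kept: list[str] = []
    kept_cols: list[np.ndarray] = []
    dropped: dict[str, str | None] = {}
    sds = X.std(axis=0)
    for j in order:
        if sds[j] == 0 or not np.isfinite(sds[j]):
            dropped[names[j]] = None
            logger.info("dropping zero-variance feature %s", names[j])
            continue
        col = X[:, j]
        rep = None
        for k_name, k_col in zip(kept, kept_cols):
            r = np.corrcoef(col, k_col)[0, 1]
            if abs(r) >= config.threshold:
                rep = k_name
                break
        if rep is None:
            kept.append(names[j])
            kept_cols.append(col)
        else:
            dropped[names[j]] = rep
    # report in original column order regardless of scan order
    kept = [n for n in names if n in set(kept)]
    return kept, dropped


class CorrelationPruner:
    """Scikit-learn-style transformer around :func:`prune_correlated`.

    Parameters
    ----------
    threshold : float, default 0.75
        Absolute Pearson correlation at or above which a feature is redundant.
    representative_rule : str, default "first_in_column_order"
        Which member of a correlated group survives.

    Attributes
    ----------
    kept_ : list of str
        Features retained after pruning, in input column order.
    dropped_ : dict
        Dropped feature -> representative kept feature (None for zero variance).
    """

    def __init__(self, threshold: float = 0.75,
                 representative_rule: str = "first_in_column_order"):
        self.threshold = threshold
        self.representative_rule = representative_rule

    def get_params(self, deep: bool = True) -> dict:
        return {"threshold": self.threshold,
                "representative_rule": self.representative_rule}

    def set_params(self, **params) -> "CorrelationPruner":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None) -> "CorrelationPruner":
        cfg = PruneConfig(self.threshold, self.representative_rule)
        self.kept_, self.dropped_ = prune_correlated(X, cfg)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "kept_"):
            raise ValidationError("CorrelationPruner is not fitted")
        return X[self.kept_]

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)


def prune_report(dropped: dict[str, str | None], matrix: pd.DataFrame) -> pd.DataFrame:
    """Tabulate dropped features with their representative and correlation."""
    rows = []
    for name, rep in dropped.items():
        if rep is None:
            rows.append({"dropped": name, "representative": "", "r": math.nan})
        else:
            r = np.corrcoef(matrix[name], matrix[rep])[0, 1]
            rows.append({"dropped": name, "representative": rep, "r": r})
    return pd.DataFrame(rows, columns=["dropped", "representative", "r"])


# ---------------------------------------------------------------------------
# standardization (population variance: transformed training sample has
# variance exactly 1)


@dataclass
class ScalerState:
    means: dict[str, float]
    stds: dict[str, float]

    def to_text(self) -> str:
        lines = ["feature\tmean\tstd"]
        for f in self.means:
            lines.append(f"{f}\t{self.means[f]!r}\t{self.stds[f]!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ScalerState":
        means, stds = {}, {}
        for line in text.strip().splitlines()[1:]:
            f, m, s = line.split("\t")
            means[f], stds[f] = float(m), float(s)
        return cls(means, stds)


def fit_standardizer(train: pd.DataFrame, columns: Sequence[str] | None = None) -> ScalerState:
    """Fit per-feature mean/SD (population) on training rows only."""
    cols = list(columns) if columns is not None else list(train.columns)
    means, stds = {}, {}
    for c in cols:
        x = train[c].to_numpy(dtype=float)
        m = float(np.mean(x))
        s = float(np.std(x))  # ddof=0
        if s == 0 or not np.isfinite(s):
            raise ValidationError(f"zero-variance training column {c!r} cannot be standardized")
        means[c], stds[c] = m, s
    return ScalerState(means, stds)


def apply_standardizer(state: ScalerState, matrix: pd.DataFrame) -> pd.DataFrame:
    """Transform a matrix with a previously fitted scaler state."""
    out = matrix.copy()
    for c, m in state.means.items():
        out[c] = (matrix[c].to_numpy(dtype=float) - m) / state.stds[c]
    return out


# ---------------------------------------------------------------------------
# stratified train/test split


@dataclass
class SplitResult:
    train_ids: list[str]
    test_ids: list[str]
    stratum_counts: dict = field(default_factory=dict)


def stratified_split(
    dataset: Dataset,
    test_fraction: float = 0.2,
    seed: int = 0,
    stratify_by: str = "potency_category",
) -> SplitResult:
    """Potency-stratified train/test split.

    Total test size is ``ceil(n_eligible * test_fraction)`` (n=122 at 0.2
    gives the 97/25 partition), allocated across strata by largest remainder
    on each stratum's exact quota. Singleton strata go to the training set
    with a warning. Reproducible under ``seed``.
    """
    if not 0 < test_fraction < 1:
        raise ValidationError("test_fraction must be in (0, 1)")
    strata: dict = {}
    for r in dataset:
        key = getattr(r, stratify_by)
        if key is None:
            raise ValidationError(f"record {r.id!r} lacks {stratify_by} for stratification")
        strata.setdefault(key, []).append(r.id)

    keys = sorted(strata)
    forced_train = []
    eligible = {}
    for k in keys:
        if len(strata[k]) == 1:
            logger.warning("stratum %r has a single record; assigned to train", k)
            forced_train.extend(strata[k])
        else:
            eligible[k] = strata[k]

    n_eligible = sum(len(v) for v in eligible.values())
    total_test = math.ceil(n_eligible * test_fraction)
    quotas = {k: len(v) * test_fraction for k, v in eligible.items()}
    counts = {k: min(math.floor(q), len(eligible[k]) - 1) for k, q in quotas.items()}
    # largest-remainder top-up, never emptying a stratum's training side
    while sum(counts.values()) < total_test:
        rem = {
            k: quotas[k] - counts[k]
            for k in eligible
            if counts[k] < len(eligible[k]) - 1
        }
        if not rem:
            break
        k_star = max(sorted(rem), key=lambda k: rem[k])
        counts[k_star] += 1

    rng = np.random.default_rng(seed)
    train_ids, test_ids = list(forced_train), []
    stratum_counts = {}
    for k in keys:
        members = strata[k]
        if k not in eligible:
            stratum_counts[k] = (len(members), 0)
            continue
        n_test = counts[k]
        picked = rng.choice(len(members), size=n_test, replace=False)
        picked_set = {members[i] for i in picked}
        test_ids.extend(m for m in members if m in picked_set)
        train_ids.extend(m for m in members if m not in picked_set)
        stratum_counts[k] = (len(members) - n_test, n_test)

    order = {rid: i for i, rid in enumerate(dataset.ids())}
    train_ids.sort(key=order.__getitem__)
    test_ids.sort(key=order.__getitem__)
    return SplitResult(train_ids, test_ids, stratum_counts)
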