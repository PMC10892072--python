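"""Plain-text model bundle serialization.

A fitted stage model is a directory of per-learner XGBoost JSON files plus
a manifest (chosen hyperparameters, bootstrap subset ids, seed, feature
list); a cascade bundle nests one stage directory per stage. Everything is
text so bundles diff and version cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import xgboost as xgb

from .cascade import TwoStageSensitizerClassifier
from .ensemble import BaggedXGBClassifier, _base_learner
from .exceptions import ValidationError


def save_bagged(model: BaggedXGBClassifier, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    # serialize the underlying boosters (JSON text); the sklearn wrapper is
    # reconstructed from the manifest on load
    for i, lr in enumerate(model.learners_):
        lr.get_booster().save_model(path / f"learner_{i}.json")
    manifest = {
        "params": model.get_params(),
        "classes": [str(c) for c in model.classes_],
        "positive_class": str(model.positive_class_),
        "negative_class": str(model.negative_class_),
        "chosen_params": model.chosen_params_,
        "cv_scores": model.cv_scores_,
        "subset_ids": [[str(i) for i in s] for s in model.subset_ids_],
        "feature_names": model.feature_names_,
        "n_learners": len(model.learners_),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_bagged(path) -> BaggedXGBClassifier:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    model = BaggedXGBClassifier(**manifest["params"])
    model.classes_ = np.asarray(manifest["classes"])
    model.positive_class_ = manifest["positive_class"]
    model.negative_class_ = manifest["negative_class"]
    model.chosen_params_ = manifest["chosen_params"]
    model.cv_scores_ = manifest["cv_scores"]
    model.subset_ids_ = manifest["subset_ids"]
    model.feature_names_ = manifest["feature_names"]
    model.n_features_in_ = len(model.feature_names_)
    model.learners_ = []
    for i in range(manifest["n_learners"]):
        lr = _base_learner(manifest["chosen_params"][i], seed=0)
        booster = xgb.Booster()
        booster.load_model(path / f"learner_{i}.json")
        lr._Booster = booster
        model.learners_.append(lr)
    return model


def save_cascade(model: TwoStageSensitizerClassifier, path, extra: dict | None = None) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    save_bagged(model.stage1_, path / "stage1")
    save_bagged(model.stage2_, path / "stage2")
    manifest = {"params": {k: v for k, v in model.get_params().items()
                           if k not in ("stage1_grid", "stage2_grid")}}
    if extra:
        manifest.update(extra)
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_cascade(path) -> TwoStageSensitizerClassifier:
    path = Path(path)
    if not (path / "manifest.json").exists():
        raise ValidationError(f"no cascade manifest under {path}")
    manifest = json.loads((path / "manifest.json").read_text())
    model = TwoStageSensitizerClassifier(**manifest["params"])
    model.stage1_ = load_bagged(path / "stage1")
    model.stage2_ = load_bagged(path / "stage2")
    from .cascade import CLASS_ORDER

    model.classes_ = np.asarray(CLASS_ORDER)
    return model
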