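import json

import numpy as np
import pandas as pd
import pytest
from xgboost import XGBClassifier

import skinsens as sk
from skinsens.exceptions import ValidationError

from conftest import SMALL_GRID


def _manual_model(learners, feature_names):
    """Assemble a BaggedXGBClassifier around pre-fitted base learners."""
    m = sk.BaggedXGBClassifier()
    m.learners_ = learners
    m.feature_names_ = list(feature_names)
    m.n_features_in_ = len(feature_names)
    m.classes_ = np.array([0, 1])
    m.positive_class_, m.negative_class_ = 1, 0
    m.chosen_params_ = [{}] * len(learners)
    m.subset_ids_ = [[]] * len(learners)
    m.cv_scores_ = [np.nan] * len(learners)
    return m


def additivity_tolerance(attribs):
    """Per-(learner, row) additivity tolerance: 1e-6, or the float32
    summation forward-error bound where single precision cannot express 1e-6.

    Tree attributions and margins are emitted in single precision; the
    additive identity is exact in the algorithm, so the residual is bounded
    by n_terms * eps32 * (|base| + sum|phi|) accumulated rounding.
    """
    eps32 = np.finfo(np.float32).eps
    n_terms = attribs.per_learner.shape[2] + 1
    l1 = np.abs(attribs.base_values) + np.abs(attribs.per_learner).sum(axis=2)
    return np.maximum(1e-6, eps32 * n_terms * l1)


class TestAdditivity:
    def test_base_plus_contributions_equals_margin_everywhere(self, fitted_bagged, blobs):
        X, _ = blobs
        at = sk.attribute(fitted_bagged, X.iloc[:50])
        recon = at.base_values.astype(np.float64) + at.per_learner.astype(np.float64).sum(axis=2)
        err = np.abs(recon - at.margins.astype(np.float64))
        assert (err < additivity_tolerance(at)).all()

    def test_averaged_attributions_are_linear_in_learners(self, fitted_bagged, blobs):
        X, _ = blobs
        at = sk.attribute(fitted_bagged, X.iloc[:30])
        # mean of per-learner reconstructions == reconstruction from averages
        lhs = (at.base_values + at.per_learner.sum(axis=2)).mean(axis=0)
        rhs = at.base_values.mean(axis=0) + at.averaged.sum(axis=1)
        np.testing.assert_allclose(lhs, rhs, atol=1e-5)  # single-precision inputs

    def test_feature_mismatch_rejected(self, fitted_bagged):
        with pytest.raises(ValidationError, match="missing"):
            sk.attribute(fitted_bagged, pd.DataFrame({"f0": [1.0]}))


class TestLocality:
    def test_single_stump_attributes_only_its_split_feature(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"used": rng.normal(0, 1, 200), "idle": rng.normal(0, 1, 200)})
        y = (X["used"] > 0).astype(int)
        stump = XGBClassifier(n_estimators=1, max_depth=1, learning_rate=1.0,
                              base_score=0.5, eval_metric="logloss").fit(X, y)
        m = _manual_model([stump], ["used", "idle"])
        at = sk.attribute(m, X.iloc[:40])
        assert np.abs(at.averaged[:, 1]).max() == 0.0
        assert np.abs(at.averaged[:, 0]).max() > 0.0

    def test_constant_model_attributes_nothing(self):
        X = pd.DataFrame({"a": np.ones(50), "b": np.ones(50)})
        y = np.r_[np.zeros(25, int), np.ones(25, int)]
        clf = XGBClassifier(n_estimators=3, max_depth=2, base_score=0.5,
                            eval_metric="logloss").fit(X, y)  # no split possible
        m = _manual_model([clf], ["a", "b"])
        at = sk.attribute(m, X.iloc[:10])
        np.testing.assert_allclose(at.averaged, 0.0, atol=1e-7)


def _tree_expectation(node, x, subset):
    """E[f(x_S, X_notS)] for one dumped tree, marginalizing by cover weights."""
    if "leaf" in node:
        return node["leaf"]
    feat = node["split"]
    kids = {c["nodeid"]: c for c in node["children"]}
    if feat in subset:
        branch = node["yes"] if x[feat] < node["split_condition"] else node["no"]
        return _tree_expectation(kids[branch], x, subset)
    total = sum(c["cover"] for c in node["children"])
    return sum(
        c["cover"] / total * _tree_expectation(c, x, subset) for c in node["children"]
    )


class TestShapleyOracle:
    def test_two_feature_tree_matches_exhaustive_shapley(self):
        # XOR-like target forces a depth-2 tree that uses both features
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"x0": rng.normal(0, 1, 400), "x1": rng.normal(0, 1, 400)})
        y = ((X["x0"] > 0) ^ (X["x1"] > 0)).astype(int)
        clf = XGBClassifier(n_estimators=1, max_depth=2, learning_rate=1.0,
                            base_score=0.5, reg_lambda=1.0,
                            eval_metric="logloss").fit(X, y)
        tree = json.loads(clf.get_booster().get_dump(with_stats=True, dump_format="json")[0])
        m = _manual_model([clf], ["x0", "x1"])
        at = sk.attribute(m, X.iloc[:25])
        for i in range(25):
            x = X.iloc[i].to_dict()
            v = {frozenset(s): _tree_expectation(tree, x, s)
                 for s in [set(), {"x0"}, {"x1"}, {"x0", "x1"}]}
            phi0 = 0.5 * (v[frozenset({"x0"})] - v[frozenset()]) + 0.5 * (
                v[frozenset({"x0", "x1"})] - v[frozenset({"x1"})]
            )
            phi1 = 0.5 * (v[frozenset({"x1"})] - v[frozenset()]) + 0.5 * (
                v[frozenset({"x0", "x1"})] - v[frozenset({"x0"})]
            )
            assert at.averaged[i, 0] == pytest.approx(phi0, abs=1e-5)
            assert at.averaged[i, 1] == pytest.approx(phi1, abs=1e-5)
            assert at.base_values[0, i] == pytest.approx(v[frozenset()], abs=1e-5)


class TestSummaryRanking:
    def test_dominant_feature_ranks_first(self, fitted_bagged, blobs):
        X, _ = blobs
        at = sk.attribute(fitted_bagged, X.iloc[:50])
        strongest = np.abs(at.averaged).mean(axis=0).argmax()
        assert sk.summary_ranking(at)[0] == at.feature_names[strongest]

    def test_all_zero_attributions_rank_alphabetically(self):
        X = pd.DataFrame({"b": np.ones(30), "a": np.ones(30), "c": np.ones(30)})
        y = np.r_[np.zeros(15, int), np.ones(15, int)]
        clf = XGBClassifier(n_estimators=2, max_depth=2, base_score=0.5,
                            eval_metric="logloss").fit(X, y)
        at = sk.attribute(_manual_model([clf], ["b", "a", "c"]), X)
        assert sk.summary_ranking(at) == ["a", "b", "c"]

    def test_ec15_ranks_first_when_it_carries_the_dominant_signal(self):
        # condition the battery so EC1.5 is the only strongly informative
        # assay: permute the other assay columns to break their association
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            ds = sk.generate(n=200, effect=2.0, seed=seed)
            X = sk.build_features(ds)
            rng = np.random.default_rng(seed)
            for col in ["C-peptide", "K-peptide", "h-CLAT", "SENS-IS_cat"]:
                X[col] = X[col].to_numpy()[rng.permutation(len(X))]
            y = np.array(
                ["sensitizer" if r.potency_category <= 4 else "non_sensitizer" for r in ds]
            )
            m = sk.BaggedXGBClassifier(param_grid=SMALL_GRID, pos_label="sensitizer",
                                       random_state=seed).fit(X, y)
            wins += sk.summary_ranking(sk.attribute(m, X))[0] == "EC1.5"
        assert wins >= 8

    def test_ec15_attribution_direction_is_negative(self):
        # higher EC1.5 (less potent) must push away from "sensitizer"
        ds = sk.generate(n=250, effect=2.0, seed=21)
        X = sk.build_features(ds)
        y = np.array(
            ["sensitizer" if r.potency_category <= 4 else "non_sensitizer" for r in ds]
        )
        m = sk.BaggedXGBClassifier(param_grid=SMALL_GRID, pos_label="sensitizer",
                                   random_state=21).fit(X, y)
        at = sk.attribute(m, X)
        j = at.feature_names.index("EC1.5")
        r = np.corrcoef(X["EC1.5"], at.averaged[:, j])[0, 1]
        assert r < 0


class TestVoteShapConcordance:
    def test_unanimous_votes_are_concordant(self, fitted_bagged, blobs):
        X, _ = blobs
        at = sk.attribute(fitted_bagged, X.iloc[:40])
        preds = fitted_bagged.predict_stage(X.iloc[:40])
        unanimous = [i for i, p in enumerate(preds) if p.vote_fraction in (0.0, 1.0)]
        assert unanimous
        table = sk.vote_shap_concordance(at, preds, positive=1)
        assert table.loc[unanimous, "concordant"].all()

    def test_close_vote_with_extreme_minority_margins_is_discordant(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"x": rng.normal(0, 1, 300)})
        y = (X["x"] > 0).astype(int)
        weak = [
            XGBClassifier(n_estimators=1, max_depth=1, learning_rate=0.05,
                          base_score=0.5, eval_metric="logloss").fit(X, y)
            for _ in range(3)
        ]
        strong = [
            XGBClassifier(n_estimators=30, max_depth=1, learning_rate=1.0,
                          base_score=0.5, eval_metric="logloss").fit(X, 1 - y)
            for _ in range(2)
        ]
        m = _manual_model(weak + strong, ["x"])
        probe = pd.DataFrame({"x": [2.0]})
        preds = m.predict_stage(probe)
        assert preds[0].vote_fraction == pytest.approx(0.6)  # 3-2 positive vote
        at = sk.attribute(m, probe)
        table = sk.vote_shap_concordance(at, preds, positive=1)
        assert not table["concordant"].iloc[0]  # summed SHAP says negative

    def test_empty_test_set_gives_empty_output(self, fitted_bagged, blobs):
        X, _ = blobs
        at = sk.attribute(fitted_bagged, X.iloc[:0])
        table = sk.vote_shap_concordance(at, [])
        assert table.empty

    def test_misaligned_inputs_rejected(self, fitted_bagged, blobs):
        X, _ = blobs
        at = sk.attribute(fitted_bagged, X.iloc[:5])
        with pytest.raises(ValidationError):
            sk.vote_shap_concordance(at, fitted_bagged.predict_stage(X.iloc[:4]))


def test_attribution_csv_long_format(fitted_bagged, blobs):
    X, _ = blobs
    at = sk.attribute(fitted_bagged, X.iloc[:6])
    out = sk.explain.attribution_csv(at) if hasattr(sk, "explain") else None
    from skinsens.explain import attribution_csv

    out = attribution_csv(at)
    assert set(out.columns) == {"id", "feature", "mean_shap"}
    assert len(out) == 6 * len(at.feature_names)
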