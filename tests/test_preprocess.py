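import numpy as np
import pandas as pd
import pytest

import skinsens as sk
from skinsens.data_model import Dataset, SubstanceRecord
from skinsens.exceptions import ValidationError
from skinsens.preprocess import (
    PruneConfig,
    ScalerState,
    apply_standardizer,
    feature_frame,
    fit_standardizer,
    prune_report,
)


class TestCapEc15:
    @pytest.mark.parametrize("value, expected", [(2500, 2000), (1500, 1500), (2000, 2000)])
    def test_capping(self, value, expected):
        assert sk.cap_ec15(value) == expected

    def test_missing_passes_through(self):
        assert sk.cap_ec15(None) is None

    @pytest.mark.parametrize("bad", [0, -5])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValidationError):
            sk.cap_ec15(bad)

    def test_monotone_and_bounded(self):
        values = np.geomspace(1e-3, 1e6, 50)
        capped = [sk.cap_ec15(v) for v in values]
        assert all(b >= a for a, b in zip(capped, capped[1:]))
        assert max(capped) <= 2000


class TestEncodeAssays:
    @pytest.mark.parametrize(
        "sensis, expected",
        [("extreme", 1), ("strong", 1), ("moderate", 1), ("weak", 1), ("negative", 0)],
    )
    def test_sensis_binarization(self, sensis, expected):
        rec = SubstanceRecord(id="a", smiles="CCO", sensis_class=sensis)
        assert sk.encode_assays(rec)["SENS-IS_cat"] == expected

    def test_missing_propagates(self):
        rec = SubstanceRecord(id="a", smiles="CCO")
        feats = sk.encode_assays(rec)
        assert feats["h-CLAT"] is None and feats["SENS-IS_cat"] is None

    def test_continuous_features_passed_through_with_cap(self):
        rec = SubstanceRecord(
            id="a", smiles="CCO", dpra_c_depletion=42.0, dpra_k_depletion=7.0,
            keratinosens_ec15=5000.0,
        )
        feats = sk.encode_assays(rec)
        assert feats["C-peptide"] == 42.0 and feats["K-peptide"] == 7.0
        assert feats["EC1.5"] == 2000.0


class TestDropIncomplete:
    def _dataset(self):
        recs = [
            SubstanceRecord(id=f"s{i}", smiles="CCO", keratinosens_ec15=10.0,
                            hclat_positive=1)
            for i in range(5)
        ]
        recs[2].keratinosens_ec15 = None
        return Dataset(recs)

    def test_removes_rows_missing_required(self):
        out = sk.drop_incomplete(self._dataset(), ["EC1.5"])
        assert len(out) == 4 and [r.id for r in out] == ["s0", "s1", "s3", "s4"]

    def test_no_required_features_is_identity(self):
        ds = self._dataset()
        assert [r.id for r in sk.drop_incomplete(ds, [])] == ds.ids()

    def test_all_incomplete_gives_empty_with_warning(self, caplog):
        ds = self._dataset()
        with caplog.at_level("WARNING"):
            out = sk.drop_incomplete(ds, ["C-peptide"])  # nobody has DPRA data
        assert len(out) == 0
        assert any("removed every record" in m for m in caplog.messages)


def brute_force_check_pruning(matrix, kept, dropped, threshold):
    """Independent all-pairs verification of the pruning postconditions."""
    corr = matrix.corr().abs()
    for a in kept:
        for b in kept:
            if a != b:
                assert corr.loc[a, b] < threshold, (a, b)
    for name, rep in dropped.items():
        if rep is not None:
            assert corr.loc[name, rep] >= threshold, (name, rep)


class TestPruneCorrelated:
    def test_identical_columns_keep_first(self):
        x = np.arange(10.0)
        m = pd.DataFrame({"A": x, "B": x})
        kept, dropped = sk.prune_correlated(m)
        assert kept == ["A"] and dropped == {"B": "A"}

    def test_independent_columns_both_kept(self):
        rng = np.random.default_rng(42)
        m = pd.DataFrame({"A": rng.normal(0, 1, 200), "B": rng.normal(0, 1, 200)})
        # textbook Pearson r, computed independently of the pruner
        a, b = m["A"] - m["A"].mean(), m["B"] - m["B"].mean()
        r = (a * b).sum() / np.sqrt((a**2).sum() * (b**2).sum())
        assert abs(r) < 0.75
        kept, dropped = sk.prune_correlated(m)
        assert kept == ["A", "B"] and not dropped

    def test_chain_resolved_greedily_in_column_order(self):
        # A-B and B-C strongly correlated (~0.85), A-C weakly (~0.5): the
        # greedy column-order scan keeps A, drops B against A, and keeps C.
        rng = np.random.default_rng(1)
        target = np.array([[1, 0.85, 0.5], [0.85, 1, 0.85], [0.5, 0.85, 1]])
        z = rng.normal(0, 1, (4000, 3)) @ np.linalg.cholesky(target).T
        m = pd.DataFrame(z, columns=["A", "B", "C"])
        kept, dropped = sk.prune_correlated(m)
        assert kept == ["A", "C"] and dropped == {"B": "A"}
        brute_force_check_pruning(m, kept, dropped, 0.75)

    @pytest.mark.parametrize("seed", range(6))
    def test_postconditions_on_random_correlated_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n, p, blocks = 120, 12, 3
        base = rng.normal(0, 1, (n, blocks))
        cols = {}
        for j in range(p):
            lam = rng.uniform(0.5, 0.95)
            cols[f"f{j:02d}"] = lam * base[:, j % blocks] + np.sqrt(1 - lam**2) * rng.normal(0, 1, n)
        m = pd.DataFrame(cols)
        kept, dropped = sk.prune_correlated(m)
        assert set(kept) | set(dropped) == set(m.columns)
        brute_force_check_pruning(m, kept, dropped, 0.75)

    def test_zero_variance_column_dropped_with_reason(self):
        m = pd.DataFrame({"A": np.arange(10.0), "Z": np.ones(10)})
        kept, dropped = sk.prune_correlated(m)
        assert kept == ["A"] and dropped == {"Z": None}
        rep = prune_report(dropped, m)
        assert rep.loc[0, "dropped"] == "Z" and np.isnan(rep.loc[0, "r"])

    def test_transformer_wrapper_and_params(self):
        m = pd.DataFrame({"A": np.arange(10.0), "B": np.arange(10.0), "C": np.arange(10.0)[::-1] ** 2})
        pruner = sk.CorrelationPruner().set_params(threshold=0.9)
        assert pruner.get_params()["threshold"] == 0.9
        out = pruner.fit_transform(m)
        assert list(out.columns) == pruner.kept_
        with pytest.raises(ValidationError):
            sk.CorrelationPruner().transform(m)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            PruneConfig(threshold=0.0)
        with pytest.raises(ValidationError):
            PruneConfig(representative_rule="magic")


class TestStandardizer:
    def test_train_columns_become_mean0_var1(self):
        rng = np.random.default_rng(0)
        train = pd.DataFrame({"a": rng.normal(3, 5, 50), "b": [1, 2, 3] * 16 + [1, 2]})
        state = fit_standardizer(train)
        out = apply_standardizer(state, train)
        assert abs(out["a"].mean()) < 1e-9 and abs(out["a"].var(ddof=0) - 1) < 1e-9
        assert abs(out["b"].mean()) < 1e-9 and abs(out["b"].var(ddof=0) - 1) < 1e-9

    def test_test_value_at_training_mean_maps_to_zero(self):
        train = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        state = fit_standardizer(train)
        out = apply_standardizer(state, pd.DataFrame({"a": [2.0]}))
        assert out["a"].iloc[0] == pytest.approx(0.0)

    def test_zero_variance_column_named_in_error(self):
        with pytest.raises(ValidationError, match="flat"):
            fit_standardizer(pd.DataFrame({"flat": [1.0, 1.0, 1.0]}))

    def test_state_text_roundtrip(self):
        state = ScalerState({"a": 1.25, "b": -3.5e-7}, {"a": 2.0, "b": 0.125})
        back = ScalerState.from_text(state.to_text())
        assert back.means == state.means and back.stds == state.stds

    def test_restandardizing_with_new_state_is_not_identity(self):
        train = pd.DataFrame({"a": [1.0, 2.0, 3.0, 10.0]})
        state = fit_standardizer(train)
        once = apply_standardizer(state, train)
        # re-applying the original state to already-scaled data shifts it again
        assert not np.allclose(apply_standardizer(state, once), once)
        # whereas refitting on the scaled data is (trivially) stable
        assert np.allclose(apply_standardizer(fit_standardizer(once), once), once)


class TestStratifiedSplit:
    def test_study_scale_split_is_97_25(self):
        ds = sk.generate(n=122, seed=5)
        res = sk.stratified_split(ds, 0.2, seed=5)
        assert (len(res.train_ids), len(res.test_ids)) == (97, 25)

    def test_single_stratum_of_ten_gives_8_2(self):
        recs = [SubstanceRecord(id=f"s{i}", smiles="CCO", potency_category=3) for i in range(10)]
        res = sk.stratified_split(Dataset(recs), 0.2, seed=0)
        assert (len(res.train_ids), len(res.test_ids)) == (8, 2)

    def test_two_equal_strata_split_evenly(self):
        recs = [SubstanceRecord(id=f"a{i}", smiles="CCO", potency_category=1) for i in range(50)]
        recs += [SubstanceRecord(id=f"b{i}", smiles="CCO", potency_category=5) for i in range(50)]
        res = sk.stratified_split(Dataset(recs), 0.2, seed=1)
        assert res.stratum_counts[1] == (40, 10) and res.stratum_counts[5] == (40, 10)

    @pytest.mark.parametrize("seed", range(0, 100, 7))
    def test_union_disjointness_and_proportions(self, seed):
        ds = sk.generate(n=122, seed=seed)
        res = sk.stratified_split(ds, 0.2, seed=seed)
        assert set(res.train_ids) | set(res.test_ids) == set(ds.ids())
        assert not set(res.train_ids) & set(res.test_ids)
        for cat, (n_train, n_test) in res.stratum_counts.items():
            size = n_train + n_test
            assert abs(n_test / size - 0.2) < 1 / size + 1e-12

    def test_reproducible_under_seed(self):
        ds = sk.generate(n=122, seed=2)
        a = sk.stratified_split(ds, 0.2, seed=9)
        b = sk.stratified_split(ds, 0.2, seed=9)
        c = sk.stratified_split(ds, 0.2, seed=10)
        assert a.test_ids == b.test_ids
        assert a.test_ids != c.test_ids

    def test_singleton_stratum_forced_to_train(self, caplog):
        recs = [SubstanceRecord(id=f"s{i}", smiles="CCO", potency_category=3) for i in range(10)]
        recs.append(SubstanceRecord(id="lonely", smiles="CCO", potency_category=1))
        with caplog.at_level("WARNING"):
            res = sk.stratified_split(Dataset(recs), 0.2, seed=0)
        assert "lonely" in res.train_ids
        assert any("single record" in m for m in caplog.messages)


def test_feature_frame_has_assays_descriptors_and_id_index(strong_dataset):
    df = feature_frame(strong_dataset)
    assert df.index.name == "id" and len(df) == len(strong_dataset)
    for f in sk.ASSAY_FEATURES:
        assert f in df.columns
    assert "roberta_embedding_mean" in df.columns
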