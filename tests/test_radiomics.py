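"""Radiomics feature selection, split, RFE and evaluation."""
import numpy as np
import pandas as pd
import pytest

from mompdose.profiles import ValidationError
from mompdose.radiomics import (FeatureTable, auc_with_delong_ci,
                                compare_pre_post, drop_shape_features,
                                infer_family, rfe_select, spearman_filter,
                                stratified_split, train_evaluate)
from mompdose.synthetic import FeatureTableConfig, gen_feature_table


def make_table(data: dict, labels=None, timepoint=None, families=None):
    df = pd.DataFrame(data)
    df.index = [f"s{i}" for i in range(len(df))]
    df.index.name = "sample_id"
    n = len(df)
    labels = pd.Series(labels if labels is not None
                       else ["a", "b"] * (n // 2) + ["a"] * (n % 2),
                       index=df.index)
    timepoint = pd.Series(timepoint if timepoint is not None else "pre",
                          index=df.index)
    families = families or {c: infer_family(c) for c in df.columns}
    return FeatureTable(df, labels, timepoint, families)


class TestShapeRemoval:
    def test_exactly_shape_features_removed(self):
        data = {f"shape_f{i}": np.arange(6.0) for i in range(3)}
        data.update({f"firstorder_f{i}": np.arange(6.0) for i in range(7)})
        table = make_table(data)
        out, dropped = drop_shape_features(table)
        assert len(out.features) == 7
        assert sorted(dropped) == [f"shape_f{i}" for i in range(3)]

    def test_no_shape_features_is_identity(self):
        table = make_table({"firstorder_a": np.arange(4.0)})
        out, dropped = drop_shape_features(table)
        assert out.features == ["firstorder_a"] and dropped == []

    def test_all_shape_warns(self):
        table = make_table({"shape_a": np.arange(4.0)})
        with pytest.warns(UserWarning, match="empty"):
            out, dropped = drop_shape_features(table)
        assert out.features == []


class TestSpearmanFilter:
    def test_uncorrelated_table_untouched(self, rng):
        table = make_table({f"firstorder_f{i}": rng.normal(size=30)
                            for i in range(5)})
        out, dropped = spearman_filter(table)
        assert dropped == [] and len(out.features) == 5

    def test_hand_computed_toy_drops_hub_feature(self):
        """f2 is a monotone transform of f1 (rho = 1); f1 is more
        correlated to f3 than f2 is, so f1 (the hub) is dropped."""
        f1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        f2 = np.exp(f1)                       # same ranks as f1
        f3 = np.array([1.0, 2.0, 3.0, 4.0, 6.0, 5.0])
        # rank correlations: rho(f1,f2)=1, rho(f1,f3)=rho(f2,f3)=0.943
        # mean |rho| is equal for f1 and f2 -> lexicographic tie-break
        # would apply; make f1 the clear hub by adding f4 ~ f1 only
        f4 = np.array([1.0, 2.0, 3.0, 5.0, 4.0, 6.0])
        table = make_table({"firstorder_f1": f1, "firstorder_f2": f2,
                            "firstorder_f3": f3, "firstorder_f4": f4})
        rho = table.data.corr(method="spearman").abs()
        assert rho.loc["firstorder_f1", "firstorder_f2"] == pytest.approx(1.0)
        out, dropped = spearman_filter(table, threshold=0.85)
        assert dropped[0] in ("firstorder_f1", "firstorder_f2")
        post = out.data.corr(method="spearman").abs().to_numpy()
        np.fill_diagonal(post, 0.0)
        assert post.max() <= 0.85 + 1e-12

    def test_idempotent(self, rng):
        base = rng.normal(size=40)
        data = {f"texture_f{i}": base + rng.normal(0, 0.1, 40)
                for i in range(4)}
        data.update({f"firstorder_f{i}": rng.normal(size=40)
                     for i in range(4)})
        once, dropped1 = spearman_filter(make_table(data))
        twice, dropped2 = spearman_filter(once)
        assert dropped2 == []
        assert twice.features == once.features

    def test_constant_feature_warns_and_survives(self, rng):
        data = {"firstorder_const": np.full(20, 3.0),
                "firstorder_x": rng.normal(size=20)}
        with pytest.warns(UserWarning, match="constant"):
            out, dropped = spearman_filter(make_table(data))
        assert "firstorder_const" in out.features


class TestStratifiedSplit:
    def test_45_samples_split_36_9(self):
        table = gen_feature_table(FeatureTableConfig(n_features=40,
                                                     n_blocks=2))
        train, val = stratified_split(table, 0.8, seed=3)
        assert train.n_samples == 36 and val.n_samples == 9

    def test_deterministic_given_seed(self):
        table = gen_feature_table(FeatureTableConfig(n_features=40,
                                                     n_blocks=2))
        a1, b1 = stratified_split(table, seed=11)
        a2, b2 = stratified_split(table, seed=11)
        assert list(a1.data.index) == list(a2.data.index)
        assert list(b1.data.index) == list(b2.data.index)

    def test_class_ratio_preserved_within_one(self):
        table = gen_feature_table(FeatureTableConfig(n_features=40,
                                                     n_blocks=2))
        train, _ = stratified_split(table, seed=5)
        global_frac = table.labels.value_counts(normalize=True)
        train_counts = train.labels.value_counts()
        for cls, frac in global_frac.items():
            expected = frac * train.n_samples
            assert abs(train_counts[cls] - expected) <= 1.0

    def test_small_class_rejected(self, rng):
        table = make_table({"firstorder_a": rng.normal(size=5)},
                           labels=["a", "a", "a", "a", "b"])
        with pytest.raises(ValidationError):
            stratified_split(table)


class TestRFE:
    def test_single_informative_feature_found(self, rng):
        n = 36
        labels = ["a", "b"] * (n // 2)
        data = {f"firstorder_f{i}": rng.normal(size=n) for i in range(30)}
        signal = np.where(np.array(labels) == "a", 1.5, -1.5)
        data["firstorder_signal"] = signal + rng.normal(0, 0.5, n)
        table = make_table(data, labels=labels)
        res = rfe_select(table, seed=2, sizes=[1, 2, 5, 10, 31])
        assert "firstorder_signal" in res.kept_features

    def test_deterministic(self, rng):
        table = gen_feature_table(FeatureTableConfig(n_features=60,
                                                     n_blocks=2, seed=5))
        train, _ = stratified_split(table, seed=5)
        r1 = rfe_select(train, seed=9, sizes=[2, 5, 10, 46])
        r2 = rfe_select(train, seed=9, sizes=[2, 5, 10, 46])
        assert r1.kept_features == r2.kept_features
        assert r1.selected_size == r2.selected_size

    def test_single_class_rejected(self, rng):
        table = make_table({"firstorder_a": rng.normal(size=12),
                            "firstorder_b": rng.normal(size=12)},
                           labels=["a"] * 12)
        with pytest.raises(ValidationError):
            rfe_select(table)


class TestEvaluation:
    def test_hand_enumerated_auc(self):
        """Scores neg {0.1, 0.4}, pos {0.35, 0.8}: 3 of 4 pairs
        concordant -> AUC 0.75."""
        auc, lo, hi = auc_with_delong_ci([0, 0, 1, 1],
                                         [0.1, 0.4, 0.35, 0.8])
        assert auc == pytest.approx(0.75)
        assert lo <= auc <= hi

    def test_matches_sklearn_empirical_auc(self, rng):
        from sklearn.metrics import roc_auc_score
        for _ in range(5):
            y = rng.integers(0, 2, 12)
            if len(np.unique(y)) < 2:
                continue
            s = rng.normal(size=12)
            auc, _, _ = auc_with_delong_ci(y, s)
            assert auc == pytest.approx(roc_auc_score(y, s))

    def test_perfect_separation_auc_one(self):
        auc, lo, hi = auc_with_delong_ci([0, 0, 1, 1, 1],
                                         [0.1, 0.2, 0.7, 0.8, 0.9])
        assert auc == 1.0 and hi == 1.0

    def test_train_evaluate_on_separable_data(self):
        table = gen_feature_table(FeatureTableConfig(n_features=40,
                                                     n_blocks=2, seed=1))
        train, val = stratified_split(table, seed=1)
        feats = [f for f in table.features if "_inf" in f]
        ev = train_evaluate(train, val, feats, seed=1)
        assert ev.n_validation == 9
        assert ev.auc >= 0.9
        assert ev.ci_low <= ev.auc <= ev.ci_high

    def test_single_class_validation_rejected(self):
        table = gen_feature_table(FeatureTableConfig(n_features=40,
                                                     n_blocks=2, seed=1))
        train, val = stratified_split(table, seed=1)
        mask = val.labels == val.labels.iloc[0]
        degenerate = val.subset_samples(val.data.index[mask])
        with pytest.raises(ValidationError):
            train_evaluate(train, degenerate, train.features[:3], seed=0)


class TestComparePrePost:
    def _pre_post_table(self, pre_values, post_values, group="g"):
        n = len(pre_values)
        data = {"firstorder_f": np.concatenate([pre_values, post_values])}
        labels = [group] * (2 * n)
        timepoint = ["pre"] * n + ["post"] * n
        return make_table(data, labels=labels, timepoint=timepoint)

    def test_identical_distributions_p_one(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        out = compare_pre_post(self._pre_post_table(v, v), "firstorder_f",
                               "g")
        assert out["p_value"] == pytest.approx(1.0)
        assert out["all_tied"] is False    # values vary, groups identical

    def test_disjoint_ranges_exact_p(self):
        pre = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        post = pre + 10.0
        out = compare_pre_post(self._pre_post_table(pre, post),
                               "firstorder_f", "g")
        assert out["p_value"] == pytest.approx(2.0 / 252.0)

    def test_invariant_to_monotone_transform(self, rng):
        pre = rng.normal(size=8)
        post = rng.normal(0.8, 1.0, 8)
        t1 = compare_pre_post(self._pre_post_table(pre, post),
                              "firstorder_f", "g")
        t2 = compare_pre_post(self._pre_post_table(np.exp(pre),
                                                   np.exp(post)),
                              "firstorder_f", "g")
        assert t1["p_value"] == pytest.approx(t2["p_value"])

    def test_missing_timepoint_rejected(self):
        v = np.array([1.0, 2.0, 3.0])
        table = make_table({"firstorder_f": v}, labels=["g"] * 3,
                           timepoint=["pre"] * 3)
        with pytest.raises(ValidationError):
            compare_pre_post(table, "firstorder_f", "g")


def test_feature_csv_roundtrip(tmp_path):
    table = gen_feature_table(FeatureTableConfig(n_features=30, n_blocks=1,
                                                 n_shape=4, seed=2))
    csv, meta = tmp_path / "t.csv", tmp_path / "m.json"
    table.to_csv(csv, meta)
    back = FeatureTable.from_csv(csv, meta)
    assert back.features == table.features
    assert back.families == table.families
    assert np.allclose(back.data.to_numpy(), table.data.to_numpy())
    # family inference from names alone matches the generator's metadata
    inferred = FeatureTable.from_csv(csv)
    assert inferred.families == table.families
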