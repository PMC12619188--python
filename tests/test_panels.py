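"""Splitting, tuning, ranking, bootstrap validation, stability selection and
permutation testing of random-forest panels."""

import numpy as np
import pandas as pd
import pytest

from gdmetab.metrics import auc_score, delong_ci, threshold_metrics, youden_threshold
from gdmetab.panels import (
    PanelEvaluation,
    RFGrid,
    SplitScheme,
    bootstrap_validate,
    enumerate_panels,
    evaluate_on_test,
    permutation_test,
    rank_features,
    select_final_panel,
    stratified_split,
    tune_random_forest,
)


def informative_data(n=100, p=8, n_informative=4, shift=1.5, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, p))
    X[y == 1, :n_informative] += shift
    cols = [f"m{j}" for j in range(p)]
    return pd.DataFrame(X, columns=cols), y


class TestStratifiedSplit:
    def test_70_30_counts(self):
        y = np.repeat([0, 1], 50)
        tr, te = stratified_split(y, SplitScheme(base_seed=1), iteration=0)
        assert len(tr) == 70 and len(te) == 30
        assert y[tr].sum() == 35 and y[te].sum() == 15
        assert np.intersect1d(tr, te).size == 0

    def test_deterministic(self):
        y = np.repeat([0, 1], 20)
        s = SplitScheme(base_seed=3)
        a = stratified_split(y, s, 2)
        b = stratified_split(y, s, 2)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        c = stratified_split(y, s, 3)
        assert not np.array_equal(a[0], c[0])

    def test_minimal_classes(self):
        y = np.array([0, 0, 1, 1])
        tr, te = stratified_split(y, SplitScheme(train_fraction=0.5), 0)
        assert len(tr) == 2 and len(te) == 2
        assert y[tr].sum() == 1 and y[te].sum() == 1

    def test_small_class_raises(self):
        with pytest.raises(ValueError):
            stratified_split(np.array([0, 1, 1]), SplitScheme(), 0)


class TestTuning:
    def test_single_point_grid_chosen(self):
        X, y = informative_data()
        model, params, _ = tune_random_forest(
            X.to_numpy(), y, RFGrid(mtry=(2,), ntree=(32,)), SplitScheme(inner_folds=3)
        )
        assert params == {"ntree": 32, "mtry": 2}
        assert model.n_estimators == 32

    def test_chosen_point_maximizes_cv_auc(self):
        X, y = informative_data(seed=1)
        grid = RFGrid(mtry=(1, 4), ntree=(16, 32))
        model, params, table = tune_random_forest(
            X.to_numpy(), y, grid, SplitScheme(inner_folds=4), seed=5
        )
        chosen = table[(table.ntree == params["ntree"]) & (table.mtry == params["mtry"])]
        assert chosen["cv_auc"].iloc[0] >= table["cv_auc"].max() - 1e-12

    def test_null_features_give_chance_cv_auc(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(70, 10))
        y = np.repeat([0, 1], 35)
        _, _, table = tune_random_forest(
            X, y, RFGrid(mtry=(3, 5), ntree=(32,)), SplitScheme(inner_folds=5), seed=2
        )
        assert abs(table["cv_auc"].mean() - 0.5) < 0.15

    def test_empty_grid_raises(self):
        X, y = informative_data()
        with pytest.raises(ValueError):
            tune_random_forest(X.to_numpy(), y, RFGrid(mtry=(), ntree=()), SplitScheme())

    def test_mtry_exceeding_features_raises(self):
        X, y = informative_data(p=3)
        with pytest.raises(ValueError):
            tune_random_forest(X.to_numpy(), y, RFGrid(mtry=(10,), ntree=(16,)), SplitScheme())


class TestRanking:
    def test_label_copy_ranked_first(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.repeat([0, 1], 40)
            X = rng.normal(size=(80, 6))
            X[:, 3] = y + 0.01 * rng.normal(size=80)
            from gdmetab.panels import _rf

            model = _rf(64, 2, seed).fit(X, y)
            ranking = rank_features(
                model, [f"m{j}" for j in range(6)], X, y, method="permutation", seed=seed
            )
            hits += ranking.index[0] == "m3"
        assert hits >= 19

    def test_gini_matches_forest_importances(self):
        X, y = informative_data(seed=3)
        from gdmetab.panels import _rf

        model = _rf(32, 2, 0).fit(X.to_numpy(), y)
        ranking = rank_features(model, X.columns, method="gini")
        assert set(ranking.index) == set(X.columns)
        assert (ranking.values[:-1] >= ranking.values[1:] - 1e-15).all()

    def test_ties_broken_by_name(self):
        class Stub:
            feature_importances_ = np.array([0.2, 0.2, 0.6])

        ranking = rank_features(Stub(), ["b", "a", "c"], method="gini")
        assert list(ranking.index) == ["c", "a", "b"]


class TestEnumerate:
    def test_top_k_rule(self):
        panels = enumerate_panels([["A", "B", "C"]], max_size=2)
        assert panels == [("A",), ("A", "B")]

    def test_duplicates_merged_across_iterations(self):
        panels = enumerate_panels([["A", "B"], ["B", "A"]], max_size=2)
        # {A}, {A,B} from iter 1; iter 2 adds only {B}
        assert panels == [("A",), ("A", "B"), ("B",)]

    def test_oversized_raises(self):
        with pytest.raises(ValueError):
            enumerate_panels([["A"]], max_size=2)


class TestBootstrap:
    def test_perfectly_separating_panel(self):
        X, y = informative_data(shift=8.0, seed=4)
        means, sds = bootstrap_validate(X, y, ("m0", "m1"), B=30, seed=0, ntree=32)
        assert means["auc"] == pytest.approx(1.0, abs=1e-9)
        assert sds["auc"] == pytest.approx(0.0, abs=1e-9)

    def test_noise_panel_near_chance(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=["a", "b", "c"])
        y = np.repeat([0, 1], 50)
        means, _ = bootstrap_validate(X, y, ("a", "b", "c"), B=100, seed=1, ntree=16)
        assert abs(means["auc"] - 0.5) < 0.1

    def test_single_replicate_sd_zero(self):
        X, y = informative_data()
        _, sds = bootstrap_validate(X, y, ("m0",), B=1, seed=0, ntree=8)
        assert all(v == 0.0 for v in sds.values())

    def test_unknown_member_raises(self):
        X, y = informative_data()
        with pytest.raises(ValueError):
            bootstrap_validate(X, y, ("nope",), B=2, seed=0)


class TestSelection:
    def ev(self, members, sd, mean):
        return PanelEvaluation(
            members=members, bootstrap_mean={"auc": mean}, bootstrap_sd={"auc": sd}
        )

    def test_lowest_sd_then_highest_auc(self):
        evals = [
            self.ev(("a", "b", "c"), 0.02, 0.90),   # size-3 SD minimum, best AUC
            self.ev(("a", "b", "d"), 0.05, 0.95),
            self.ev(("a",), 0.01, 0.80),
        ]
        final = select_final_panel(evals)
        assert final.members == ("a", "b", "c")
        assert final.final and final.stable_within_size

    def test_sd_tie_higher_auc_wins(self):
        evals = [self.ev(("a",), 0.02, 0.70), self.ev(("b",), 0.02, 0.75)]
        assert select_final_panel(evals).members == ("b",)

    def test_auc_tie_smaller_panel_wins(self):
        evals = [self.ev(("a",), 0.02, 0.9), self.ev(("b", "c"), 0.01, 0.9)]
        assert select_final_panel(evals).members == ("a",)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            select_final_panel([])


class TestEvaluateOnTest:
    def test_separable_panel_auc_one(self):
        X, y = informative_data(shift=6.0, seed=5)
        tr, te = stratified_split(y, SplitScheme(base_seed=0), 0)
        out = evaluate_on_test(X, y, ("m0", "m1"), tr, te, ntree=32)
        assert out["auc"] == 1.0
        assert out["sensitivity"] == 1.0 and out["specificity"] == 1.0

    def test_overlap_raises(self):
        X, y = informative_data()
        with pytest.raises(ValueError):
            evaluate_on_test(X, y, ("m0",), np.arange(10), np.arange(5, 15))

    def test_single_class_test_raises(self):
        X, y = informative_data()
        with pytest.raises(ValueError):
            evaluate_on_test(X, y, ("m0",), np.arange(20, 90), np.arange(0, 10))

    def test_no_information_leakage_from_test_labels(self):
        """Permuting the held-out labels must not change the fitted model's
        test-set scores (train-only fitting)."""
        X, y = informative_data(seed=6)
        tr, te = stratified_split(y, SplitScheme(base_seed=1), 0)
        out1 = evaluate_on_test(X, y, ("m0", "m2"), tr, te, ntree=16, seed=3)
        y2 = y.copy()
        rng = np.random.default_rng(0)
        y2[te] = rng.permutation(y2[te])
        out2 = evaluate_on_test(X, y2, ("m0", "m2"), tr, te, ntree=16, seed=3)
        # same model, same scores: metrics differ only through the labels;
        # rerunning with the original labels must reproduce out1 exactly
        out3 = evaluate_on_test(X, y, ("m0", "m2"), tr, te, ntree=16, seed=3)
        assert out1 == out3
        assert out2 != out1  # labels changed, so the metrics did


class TestMetrics:
    def test_auc_matches_pairwise_count(self):
        """AUC equals the tie-aware Mann-Whitney pair count (n <= 30)."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 31))
            y = np.zeros(n, dtype=int)
            y[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            if y.sum() in (0, n):
                continue
            s = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
            pos, neg = s[y == 1], s[y == 0]
            pairs = sum(
                1.0 if a > b else (0.5 if a == b else 0.0) for a in pos for b in neg
            )
            assert auc_score(y, s) == pytest.approx(pairs / (len(pos) * len(neg)))

    def test_auc_antisymmetry_under_label_swap(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        s = rng.normal(size=30)
        assert auc_score(1 - y, s) == pytest.approx(1 - auc_score(y, s))

    def test_youden_threshold_separable(self):
        y = np.repeat([0, 1], 5)
        s = np.concatenate([np.arange(5), np.arange(10, 15)]).astype(float)
        thr = youden_threshold(y, s)
        tm = threshold_metrics(y, s, thr)
        assert tm["sensitivity"] == 1.0 and tm["specificity"] == 1.0

    def test_delong_ci_brackets_auc(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 30)
        s = rng.normal(size=60) + 0.8 * y
        auc, lo, hi = delong_ci(y, s)
        assert lo <= auc <= hi
        assert auc == pytest.approx(auc_score(y, s))


class TestPermutation:
    def test_add_one_formula(self):
        calls = {"n": 0}

        def metric(labels, seed):
            calls["n"] += 1
            return 1.0 if calls["n"] == 1 else 0.0  # observed beats every null

        res = permutation_test(metric, np.repeat([0, 1], 10), P=100, seed=0)
        assert res.p_value == pytest.approx(1 / 101)
        assert len(res.null_values) == 100

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            permutation_test(lambda y, s: 0.5, np.repeat([0, 1], 5), P=0)
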