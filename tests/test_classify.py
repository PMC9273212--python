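"""The bootstrap protocol: resampling geometry, feature selection, the
balanced forest, depth tuning, evaluation reports and aggregation."""

import numpy as np
import pandas as pd
import pytest

from oracles import ranksum_exact_p

from cfrnaflow.classify import (
    BootstrapSpec,
    ClassificationError,
    aggregate_feature_importance,
    auroc,
    compare_feature_sets,
    draw_bootstrap,
    evaluate_binary,
    evaluate_multiclass,
    fit_balanced_random_forest,
    select_features_binary,
    select_features_multiclass,
    tune_depth,
)
from cfrnaflow.differential import ranksum_test


def _expr(rng, n_features, sample_ids):
    return pd.DataFrame(rng.normal(size=(n_features, len(sample_ids))),
                        index=[f"f{i}" for i in range(n_features)],
                        columns=sample_ids)


class TestDrawBootstrap:
    def test_holdout_fraction_near_expectation(self, rng):
        ids = [f"S{i}" for i in range(100)]
        fractions = [len(draw_bootstrap(ids, rng)[1]) / 100
                     for _ in range(100)]
        assert 0.33 <= np.mean(fractions) <= 0.41  # (1 - 1/n)^n ~ 0.366

    def test_holdout_disjoint_from_train(self, rng):
        ids = [f"S{i}" for i in range(50)]
        train, holdout = draw_bootstrap(ids, rng)
        assert len(train) == 50
        assert set(train) & set(holdout) == set()
        assert set(train) | set(holdout) == set(ids)

    def test_seeded_draws_identical(self):
        ids = [f"S{i}" for i in range(30)]
        a = draw_bootstrap(ids, np.random.default_rng(5))
        b = draw_bootstrap(ids, np.random.default_rng(5))
        assert a == b

    def test_class_coverage_enforced(self, rng):
        ids = [f"S{i}" for i in range(20)]
        labels = pd.Series(["a"] * 10 + ["b"] * 10, index=ids)
        for _ in range(20):
            train, holdout = draw_bootstrap(ids, rng, labels=labels)
            assert set(labels.loc[train]) == {"a", "b"}
            assert set(labels.loc[holdout]) == {"a", "b"}

    def test_singleton_class_errors_with_class_name(self, rng):
        ids = [f"S{i}" for i in range(10)]
        labels = pd.Series(["a"] * 9 + ["rare"], index=ids)
        with pytest.raises(ClassificationError, match="rare"):
            draw_bootstrap(ids, rng, labels=labels, max_redraws=20)


class TestFeatureSelection:
    def test_union_size_bounded(self, rng):
        ids = [f"S{i}" for i in range(40)]
        expr = _expr(rng, 2000, ids)
        labels = ["a"] * 20 + ["b"] * 20
        spec = BootstrapSpec(top_k_features=50, n_subsample_rounds=10)
        selected = select_features_binary(expr, labels, spec,
                                          np.random.default_rng(0))
        assert len(selected) <= 500

    def test_perfectly_separating_feature_always_selected(self, rng):
        ids = [f"S{i}" for i in range(30)]
        expr = _expr(rng, 300, ids)
        labels = ["a"] * 15 + ["b"] * 15
        expr.loc["f42"] = [0.0] * 15 + [10.0] * 15
        spec = BootstrapSpec(top_k_features=5, n_subsample_rounds=10)
        selected = select_features_binary(expr, labels, spec,
                                          np.random.default_rng(1))
        assert "f42" in selected

    def test_constant_features_deterministic_tie_break(self):
        ids = [f"S{i}" for i in range(20)]
        expr = pd.DataFrame(np.ones((200, 20)),
                            index=[f"f{i}" for i in range(200)], columns=ids)
        labels = ["a"] * 10 + ["b"] * 10
        spec = BootstrapSpec(top_k_features=50, n_subsample_rounds=3)
        a = select_features_binary(expr, labels, spec, np.random.default_rng(7))
        b = select_features_binary(expr, labels, spec, np.random.default_rng(7))
        assert a == b
        assert a == [f"f{i}" for i in range(50)]  # stable feature order

    def test_two_class_multiclass_reduces_to_binary(self, rng):
        ids = [f"S{i}" for i in range(24)]
        expr = _expr(rng, 150, ids)
        labels = ["a"] * 12 + ["b"] * 12
        spec = BootstrapSpec(top_k_features=10, n_subsample_rounds=4)
        a = select_features_binary(expr, labels, spec, np.random.default_rng(3))
        b = select_features_multiclass(expr, labels, spec,
                                       np.random.default_rng(3))
        assert a == b

    def test_class_discriminating_feature_found_in_multiclass(self, rng):
        ids = [f"S{i}" for i in range(50)]
        expr = _expr(rng, 200, ids)
        labels = np.repeat(["a", "b", "c", "d", "e"], 10)
        expr.loc["f10"] = np.where(labels == "c", 8.0, 0.0) + \
            rng.normal(0, 0.1, 50)
        spec = BootstrapSpec(top_k_features=20, n_subsample_rounds=1)
        selected = select_features_multiclass(expr, labels, spec,
                                              np.random.default_rng(4))
        assert "f10" in selected


class TestBalancedForest:
    def test_per_tree_class_counts_equal(self, rng):
        x = rng.normal(size=(30, 10))
        y = np.array(["a"] * 22 + ["b"] * 8)
        model = fit_balanced_random_forest(x, y, depth=None, n_trees=10,
                                           rng=rng)
        for idx in model.tree_sample_indices_:
            counts = pd.Series(y[idx]).value_counts()
            assert counts["a"] == counts["b"] == 8  # minority size

    def test_separable_data_perfect_training_auroc(self, rng):
        x = np.vstack([rng.normal(0, 1, size=(20, 5)),
                       rng.normal(8, 1, size=(20, 5))])
        y = np.array(["neg"] * 20 + ["pos"] * 20)
        model = fit_balanced_random_forest(x, y, depth=None, n_trees=25,
                                           rng=rng)
        proba = model.predict_proba(x)[:, 1]
        assert auroc(proba, y == "pos") == 1.0

    def test_seeded_fit_reproducible(self, rng):
        x = rng.normal(size=(40, 8))
        y = np.array(["a", "b"] * 20)
        p1 = fit_balanced_random_forest(x, y, 5, 10,
                                        np.random.default_rng(9)).predict_proba(x)
        p2 = fit_balanced_random_forest(x, y, 5, 10,
                                        np.random.default_rng(9)).predict_proba(x)
        np.testing.assert_array_equal(p1, p2)


class TestTuneDepth:
    def test_singleton_grid_short_circuits(self, rng):
        spec = BootstrapSpec(depth_grid=(4,))
        assert tune_depth(np.zeros((10, 2)), ["a", "b"] * 5, spec, rng) == 4

    def test_noise_data_prefers_smallest_depth(self):
        wins = 0
        for seed in range(7):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(60, 20))
            y = np.array(["a", "b"] * 30)
            spec = BootstrapSpec(depth_grid=(3, None), cv_folds=3, n_trees=20)
            if tune_depth(x, y, spec, rng) == 3:
                wins += 1
        assert wins >= 4  # ties and noise both favor the small depth

    def test_deterministic_given_seed(self, rng):
        x = np.random.default_rng(2).normal(size=(40, 10))
        y = np.array(["a", "b"] * 20)
        spec = BootstrapSpec(depth_grid=(3, 5), cv_folds=3, n_trees=10)
        d1 = tune_depth(x, y, spec, np.random.default_rng(0))
        d2 = tune_depth(x, y, spec, np.random.default_rng(0))
        assert d1 == d2


class TestAuroc:
    def test_perfect_and_tied_scores(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert auroc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1]) == 0.5

    def test_half_concordant_pairs(self):
        assert auroc([0.9, 0.4, 0.6, 0.2], [1, 0, 0, 1]) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ClassificationError):
            auroc([0.1, 0.9], [1, 1])

    def test_matches_mann_whitney_identity(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30).astype(bool)
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        u, _ = ranksum_test(scores[labels], scores[~labels],
                            alternative="two-sided")
        assert auroc(scores, labels) == pytest.approx(
            u / (labels.sum() * (~labels).sum()))


def _binary_setup(rng, n=40, n_features=100, signal=4.0):
    ids = [f"S{i}" for i in range(n)]
    labels = pd.Series(["HD"] * (n // 2) + ["cancer"] * (n // 2), index=ids)
    expr = _expr(rng, n_features, ids)
    expr.iloc[:10, n // 2:] += signal
    return expr, labels


SMALL_SPEC = BootstrapSpec(n_replicates=4, n_subsample_rounds=3,
                           top_k_features=10, n_trees=15,
                           depth_grid=(3, None), cv_folds=2, seed=5)


class TestEvaluateBinary:
    def test_report_contract(self, rng):
        expr, labels = _binary_setup(rng)
        report = evaluate_binary(expr, labels, SMALL_SPEC,
                                 positive_label="cancer")
        assert len(report.auroc_distribution) == 4
        assert all(0 <= a <= 1 for a in report.auroc_distribution)
        assert report.oob_roc is not None and report.oob_auroc is not None
        for rep in report.replicates:
            assert set(rep.holdout_ids) & set(rep.train_ids) == set()
            assert len(rep.train_ids) == expr.shape[1]

    def test_bitwise_reproducible(self, rng):
        expr, labels = _binary_setup(rng)
        r1 = evaluate_binary(expr, labels, SMALL_SPEC, positive_label="cancer")
        r2 = evaluate_binary(expr, labels, SMALL_SPEC, positive_label="cancer")
        assert r1.to_json_dict() == r2.to_json_dict()

    def test_holdout_never_read_before_prediction(self, rng):
        """Leakage control: the instrumentation hook must show that holdout
        expression is only touched after the model is fitted."""
        expr, labels = _binary_setup(rng)
        events = []
        evaluate_binary(expr, labels, SMALL_SPEC, positive_label="cancer",
                        hook=lambda name, payload: events.append((name, payload)))
        per_rep = {}
        for name, payload in events:
            per_rep.setdefault(payload["replicate"], []).append(name)
        for names in per_rep.values():
            assert names.index("holdout_read") > names.index("model_fitted")
        starts = [p for n, p in events if n == "train_extracted"]
        for payload in starts:
            assert set(payload["train_ids"]) & set(payload["holdout_ids"]) == set()


class TestEvaluateMulticlass:
    @pytest.fixture(scope="class")
    def report(self):
        rng = np.random.default_rng(31)
        ids = [f"S{i}" for i in range(60)]
        labels = pd.Series(np.repeat(["a", "b", "c"], 20), index=ids)
        expr = _expr(rng, 120, ids)
        for j, c in enumerate(["a", "b", "c"]):
            expr.iloc[j * 10:(j + 1) * 10, (labels == c).to_numpy()] += 3.0
        return evaluate_multiclass(expr, labels, SMALL_SPEC)

    def test_confusion_rows_sum_to_one(self, report):
        np.testing.assert_allclose(report.confusion_matrix.sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_top2_at_least_top1_everywhere(self, report):
        assert (report.top2_recall.to_numpy()
                >= report.top1_recall.to_numpy() - 1e-12).all()

    def test_fewer_than_three_classes_rejected(self, rng):
        expr, labels = _binary_setup(rng)
        with pytest.raises(ClassificationError):
            evaluate_multiclass(expr, labels, SMALL_SPEC)


class TestAggregation:
    def test_frequencies_match_manual_recount(self, rng):
        expr, labels = _binary_setup(rng)
        report = evaluate_binary(expr, labels, SMALL_SPEC,
                                 positive_label="cancer")
        table = aggregate_feature_importance(report.replicates,
                                             rank_cutoff=5, min_frequency=1)
        for _, row in table.iterrows():
            manual = sum(
                1 for rep in report.replicates
                if rep.importance_ranks.get(row["feature"], 10 ** 9) <= 5)
            assert row["frequency"] == manual

    def test_min_frequency_threshold_applied(self, rng):
        expr, labels = _binary_setup(rng)
        report = evaluate_binary(expr, labels, SMALL_SPEC,
                                 positive_label="cancer")
        table = aggregate_feature_importance(report.replicates,
                                             rank_cutoff=5, min_frequency=4)
        assert (table["frequency"] >= 4).all()

    def test_never_selected_feature_absent(self, rng):
        expr, labels = _binary_setup(rng)
        report = evaluate_binary(expr, labels, SMALL_SPEC,
                                 positive_label="cancer")
        table = aggregate_feature_importance(report.replicates,
                                             rank_cutoff=50, min_frequency=1)
        selected_ever = set().union(*[set(r.selected_features)
                                      for r in report.replicates])
        assert set(table["feature"]) <= selected_ever

    def test_empty_replicates_error(self):
        with pytest.raises(ClassificationError):
            aggregate_feature_importance([], 50, 40)


class TestCompareFeatureSets:
    def test_exact_enumeration_example(self):
        p = compare_feature_sets([0.6, 0.7, 0.8], [0.1, 0.2, 0.3])
        assert p == pytest.approx(1 / 20)

    def test_identical_distributions_not_significant(self):
        assert compare_feature_sets([0.5, 0.6, 0.7], [0.5, 0.6, 0.7]) >= 0.5

    def test_one_sidedness(self):
        assert compare_feature_sets([0.1, 0.2, 0.3], [0.6, 0.7, 0.8]) > 0.9

    def test_matches_enumeration_oracle(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=5)
        assert compare_feature_sets(a, b) == pytest.approx(
            ranksum_exact_p(a, b, "greater"), abs=1e-12)
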