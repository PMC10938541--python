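"""Splits, Bayesian tuning, bootstrap evaluation and model selection."""

import numpy as np
import pandas as pd
import pytest

from repclass.modeling import (
    ModelReport,
    SearchConfig,
    bayesian_optimize,
    bootstrap_evaluate,
    multi_split_evaluation,
    select_best_model,
    split_cohort,
    tune_and_fit,
)
from repclass.repertoire_io import CohortMatrix


def _report(family, mean_auc, n_features=3):
    return ModelReport(
        family=family,
        selector="LGB",
        feature_set=[f"CF{i}F" for i in range(n_features)],
        hyperparameters={},
        per_split_auc=[mean_auc],
        mean_auc=mean_auc,
        bootstrap_scores=[mean_auc],
        bootstrap_mean=mean_auc,
        confusion={"TP": 0, "FP": 0, "TN": 0, "FN": 0},
        roc_fpr=[0, 1],
        roc_mean_tpr=[0, 1],
        seed=0,
    )


def _separable(n=40, n_features=3, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(0, 0.3, (n_features, n)) + y * 2.0
    df = pd.DataFrame(X, index=[f"CFEAT{i}F" for i in range(n_features)],
                      columns=[f"s{i}" for i in range(n)])
    labels = pd.Series(np.where(y == 1, "OC", "HD"), index=df.columns)
    return CohortMatrix(values=df, labels=labels)


class TestSplitCohort:
    def test_partition_laws(self, tiny_matrix):
        train, test = split_cohort(tiny_matrix, 6, seed=0)
        assert test.n_samples == 6
        assert train.n_samples == tiny_matrix.n_samples - 6
        assert set(train.sample_ids) | set(test.sample_ids) == set(tiny_matrix.sample_ids)
        assert not set(train.sample_ids) & set(test.sample_ids)

    def test_stratification_preserves_ratio(self, tiny_matrix):
        train, test = split_cohort(tiny_matrix, 6, seed=1)
        full_ratio = np.mean(tiny_matrix.y())
        assert abs(np.mean(test.y()) - full_ratio) < 0.25

    def test_determinism(self, tiny_matrix):
        a = split_cohort(tiny_matrix, 6, seed=5)
        b = split_cohort(tiny_matrix, 6, seed=5)
        assert a[1].sample_ids == b[1].sample_ids

    def test_bad_test_size(self, tiny_matrix):
        with pytest.raises(ValueError):
            split_cohort(tiny_matrix, tiny_matrix.n_samples, seed=0)


class TestBayesianOptimize:
    def test_one_point_space_forced(self):
        calls = []

        def objective(p):
            calls.append(p)
            return 0.5

        space = {"x": ("cat", ["only"])}
        best, trials = bayesian_optimize(objective, space, 2, 4, seed=0)
        assert best == {"x": "only"}
        assert len(trials) == 4

    def test_concave_objective_found(self):
        """A smooth 1-D concave objective is optimized to near its peak in
        at least 95% of seeds within the standard budget."""
        hits = 0
        for seed in range(20):
            best, _ = bayesian_optimize(
                lambda p: -((p["x"] - 0.63) ** 2),
                {"x": ("float", 0.0, 1.0)},
                n_init=5,
                n_iter=25,
                seed=seed,
            )
            hits += abs(best["x"] - 0.63) < 0.08
        assert hits >= 19

    def test_all_failures_raise(self):
        def broken(p):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="failed"):
            bayesian_optimize(broken, {"x": ("float", 0, 1)}, 2, 3, seed=0)

    def test_int_and_log_decoding(self):
        seen = []

        def objective(p):
            seen.append(p)
            return 0.0

        bayesian_optimize(
            objective,
            {"n": ("int", 2, 9), "c": ("logfloat", 1e-3, 1e3)},
            3, 3, seed=1,
        )
        for p in seen:
            assert 2 <= p["n"] <= 9 and isinstance(p["n"], int)
            assert 1e-3 <= p["c"] <= 1e3


class TestTuneAndFit:
    @pytest.mark.parametrize("family", ["lda", "gbm", "logreg"])
    def test_separable_reaches_auc_one(self, family):
        m = _separable()
        tuned = tune_and_fit(m, family, bo_init=3, bo_iters=5, seed=0)
        assert tuned.val_auc == pytest.approx(1.0)

    def test_deterministic(self):
        m = _separable()
        a = tune_and_fit(m, "logreg", bo_init=3, bo_iters=6, seed=4)
        b = tune_and_fit(m, "logreg", bo_init=3, bo_iters=6, seed=4)
        assert a.params == b.params


class TestBootstrapEvaluate:
    def test_n_scores_and_mean(self):
        m = _separable(n=40)
        train, test = split_cohort(m, 10, seed=2)
        scores, mean, sd = bootstrap_evaluate("lda", {}, train, test, n=5, seed=0)
        assert len(scores) == 5
        assert mean == pytest.approx(np.mean(scores))
        assert all(s == pytest.approx(1.0) for s in scores)  # separable

    def test_bad_n(self):
        m = _separable()
        train, test = split_cohort(m, 10, seed=2)
        with pytest.raises(ValueError):
            bootstrap_evaluate("lda", {}, train, test, n=0)


class TestMultiSplit:
    def test_report_invariants_on_separable_data(self):
        m = _separable(n=40)
        cfg = SearchConfig(bo_init=2, bo_iters=3, n_splits=3, test_size=10)
        rep = multi_split_evaluation(m, list(m.clone_keys), "lda",
                                     n_splits=3, seed=1, config=cfg)
        assert len(rep.per_split_auc) == 3
        assert rep.mean_auc == pytest.approx(np.mean(rep.per_split_auc))
        assert rep.mean_auc == pytest.approx(1.0)
        conf = rep.confusion
        assert sum(conf.values()) == m.n_samples
        assert all(0 <= a <= 1 for a in rep.per_split_auc)

    def test_label_permutation_gives_chance_auc(self):
        """With permuted labels the mean AUC collapses to chance."""
        rng = np.random.default_rng(0)
        m = _separable(n=44, seed=3)
        perm = rng.permutation(m.labels.to_numpy())
        null = CohortMatrix(values=m.values, labels=pd.Series(perm, index=m.sample_ids))
        cfg = SearchConfig(bo_init=2, bo_iters=3, n_splits=8, test_size=12)
        rep = multi_split_evaluation(null, list(null.clone_keys), "lda",
                                     n_splits=8, seed=2, config=cfg)
        assert 0.3 <= rep.mean_auc <= 0.7

    def test_reproducible(self):
        m = _separable(n=30)
        cfg = SearchConfig(bo_init=2, bo_iters=3, n_splits=2, test_size=8)
        a = multi_split_evaluation(m, list(m.clone_keys), "logreg", 2, seed=7, config=cfg)
        b = multi_split_evaluation(m, list(m.clone_keys), "logreg", 2, seed=7, config=cfg)
        assert a.per_split_auc == b.per_split_auc
        assert a.hyperparameters == b.hyperparameters


class TestSelectBestModel:
    def test_single_and_max(self):
        a, b = _report("gbm", 0.9), _report("lda", 0.95)
        assert select_best_model([a]) is a
        assert select_best_model([a, b]) is b

    def test_full_grid_equals_brute_force_max(self):
        rng = np.random.default_rng(11)
        reports = [
            _report(f, float(rng.uniform(0.5, 1.0)))
            for f in ("gbm", "knn", "lda", "lgb", "logreg", "rf", "svc", "xgb")
            for _ in range(4)  # 8 families x 4 selectors
        ]
        best = select_best_model(reports)
        assert best.mean_auc == max(r.mean_auc for r in reports)

    def test_tie_prefers_fewer_features_then_name(self):
        a = _report("xgb", 0.9, n_features=5)
        b = _report("gbm", 0.9, n_features=3)
        c = _report("lda", 0.9, n_features=3)
        assert select_best_model([a, b, c]).family == "gbm"


class TestNoTestLeakage:
    def test_selection_ignores_test_columns(self, separable_matrix):
        """Corrupting the held-out columns must not change feature selection
        or tuned hyperparameters computed on the training partition."""
        from repclass.feature_selection import rank_common_clones, select_from_model

        train, test = split_cohort(separable_matrix, 6, seed=3)
        corrupted_values = separable_matrix.values.copy()
        rng = np.random.default_rng(0)
        corrupted_values[test.sample_ids] = rng.random(
            (len(corrupted_values), test.n_samples)
        )
        corrupted = CohortMatrix(values=corrupted_values, labels=separable_matrix.labels)
        train2 = corrupted.restrict_samples(train.sample_ids)

        cand1 = rank_common_clones(train, 50)
        cand2 = rank_common_clones(train2, 50)
        assert cand1 == cand2

        fs1 = select_from_model(train.restrict_clones(cand1), train.y(), "LGB", 5, seed=1)
        fs2 = select_from_model(train2.restrict_clones(cand2), train2.y(), "LGB", 5, seed=1)
        assert fs1.clone_keys == fs2.clone_keys

        t1 = tune_and_fit(train.restrict_clones(fs1.clone_keys), "lda", 2, 3, seed=1)
        t2 = tune_and_fit(train2.restrict_clones(fs2.clone_keys), "lda", 2, 3, seed=1)
        assert t1.params == t2.params
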