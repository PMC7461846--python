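"""Cross-validation plans, confound regression, metrics, experiment driver."""

import numpy as np
import pandas as pd
import pytest

from deepchronnect.training import (
    apply_confounds,
    audit_leakage,
    evaluate,
    fit_confounds,
    make_folds,
    run_experiment,
)


class TestMakeFolds:
    def test_large_cohort_fold_sizes(self):
        plan = make_folds([f"s{i}" for i in range(1050)], k=10, seed=0)
        assert plan.k == 10
        assert all(len(f["test"]) == 105 for f in plan.folds)

    def test_leave_one_subject_out_degenerate(self):
        subs = [f"s{i}" for i in range(6)]
        plan = make_folds(subs, k=6, seed=1)
        assert sorted(s for f in plan.folds for s in f["test"]) == sorted(subs)
        assert all(len(f["test"]) == 1 and len(f["val"]) == 1 for f in plan.folds)

    def test_partition_and_disjointness_over_seeds(self):
        subs = [f"s{i}" for i in range(37)]
        for seed in range(100):
            plan = make_folds(subs, k=5, seed=seed)
            plan.check_partition(subs)  # raises on any violation

    def test_runs_never_split_across_folds(self):
        # folds are drawn over subjects, so any run->subject map keeps a
        # subject's runs together; checked over 100 random cohorts
        rng = np.random.default_rng(0)
        for _ in range(100):
            n_sub = int(rng.integers(10, 30))
            subs = [f"s{i}" for i in range(n_sub)]
            runs = [(f"{s}_r{k}", s) for s in subs
                    for k in range(int(rng.integers(1, 4)))]
            plan = make_folds(subs, k=5, seed=int(rng.integers(2**31)))
            fold_of = {s: i for i, f in enumerate(plan.folds) for s in f["test"]}
            for run_id, s in runs:
                assert fold_of[s] == fold_of[run_id.split("_")[0]]

    def test_stratified_folds_balance_labels(self):
        subs = [f"s{i}" for i in range(40)]
        labels = {s: i % 2 for i, s in enumerate(subs)}
        plan = make_folds(subs, k=4, seed=3, stratify_labels=labels)
        for f in plan.folds:
            counts = np.bincount([labels[s] for s in f["test"]], minlength=2)
            assert abs(counts[0] - counts[1]) <= 1

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], k=3)


class TestConfounds:
    def test_zero_effect_gives_centered_scores(self, rng):
        scores = rng.standard_normal(200)
        covs = rng.standard_normal((200, 3))
        model = fit_confounds(scores, covs)
        resid = apply_confounds(model, scores, covs)
        np.testing.assert_allclose(model.coef, 0.0, atol=0.2)
        np.testing.assert_allclose(resid.mean(), 0.0, atol=0.05)

    def test_training_residuals_orthogonal_to_covariates(self, rng):
        age = rng.uniform(20, 40, size=100)
        scores = 2.0 * age + rng.standard_normal(100)
        model = fit_confounds(scores, age[:, None])
        resid = apply_confounds(model, scores, age[:, None])
        assert abs(np.corrcoef(resid, age)[0, 1]) < 1e-10

    def test_out_of_sample_residuals_not_orthogonal(self, rng):
        # coefficients fitted on train and applied to test leave some
        # covariate correlation in the test residuals — allowed behavior
        age_tr = rng.uniform(20, 40, 50)
        age_te = rng.uniform(20, 40, 50)
        y_tr = 2 * age_tr + rng.standard_normal(50)
        y_te = 2 * age_te + rng.standard_normal(50)
        model = fit_confounds(y_tr, age_tr[:, None])
        resid = apply_confounds(model, y_te, age_te[:, None])
        assert resid.shape == (50,)
        assert np.isfinite(np.corrcoef(resid, age_te)[0, 1])

    def test_rank_deficient_design_rejected(self, rng):
        age = rng.uniform(20, 40, 30)
        covs = np.column_stack([age, age])  # duplicated column
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_confounds(rng.standard_normal(30), covs)


class TestEvaluate:
    def test_perfect_predictions(self):
        m = evaluate(np.array([0, 1, 1, 0]), np.array([0, 1, 1, 0]),
                     "classification", y_score=np.array([0.1, 0.9, 0.8, 0.2]))
        assert m["accuracy"] == 1.0 and m["auc"] == 1.0
        m = evaluate(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]),
                     "regression")
        assert m["pearson_r"] == pytest.approx(1.0) and m["mae"] == 0.0

    def test_auc_by_pairwise_rank_counting(self):
        truth = np.array([0, 0, 1, 1])
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        m = evaluate(truth, (scores > 0.5).astype(int), "classification",
                     y_score=scores)
        # 3 of 4 positive/negative pairs correctly ordered
        assert m["auc"] == pytest.approx(0.75)

    def test_shift_invariance_of_pearson(self, rng):
        y = rng.standard_normal(50)
        m = evaluate(y, y + 3.0, "regression")
        assert m["pearson_r"] == pytest.approx(1.0)
        assert m["mae"] == pytest.approx(3.0)

    def test_constant_predictions_warn_zero_r(self, rng):
        with pytest.warns(UserWarning, match="constant"):
            m = evaluate(rng.standard_normal(20), np.zeros(20), "regression")
        assert m["pearson_r"] == 0.0


def _tiny_estimator():
    return {"conv_kernels": (2, 3), "conv_channels": 3, "lstm_hidden": 4,
            "dropout": 0.0, "learning_rate": 5e-3, "lr_decay": 1.0,
            "batch_size": 4, "max_epochs": 30, "patience": 30}


class TestRunExperiment:
    def test_separable_cohort_reaches_high_accuracy(self, rng):
        n = 30
        X = rng.standard_normal((n, 20, 6))
        y = np.tile([0, 1], n // 2)
        X[y == 1, :, :2] += 1.5
        subs = [f"s{i}" for i in range(n)]
        res = run_experiment(X, subs, dict(zip(subs, y)), task="classification",
                             n_folds=3, seed=0, estimator_kwargs=_tiny_estimator())
        assert res.pooled_metrics["accuracy"] >= 0.85
        assert audit_leakage(res)

    def test_null_labels_near_chance(self, rng):
        n = 40
        X = rng.standard_normal((n, 20, 6))
        y = rng.integers(0, 2, size=n)
        y[: n // 2] = np.tile([0, 1], n // 4)  # keep both classes present
        subs = [f"s{i}" for i in range(n)]
        kw = _tiny_estimator() | {"max_epochs": 5}
        res = run_experiment(X, subs, dict(zip(subs, y)), task="classification",
                             n_folds=4, seed=1, estimator_kwargs=kw)
        assert 0.2 <= res.pooled_metrics["accuracy"] <= 0.8

    def test_multi_run_subject_aggregation(self, rng):
        # 10 subjects x 2 runs: predictions averaged to one row per subject
        subs = [f"s{i}" for i in range(10) for _ in range(2)]
        X = rng.standard_normal((20, 20, 6))
        y = {f"s{i}": i % 2 for i in range(10)}
        for r, s in enumerate(subs):
            if y[s]:
                X[r, :, :2] += 1.0
        kw = _tiny_estimator() | {"max_epochs": 6}
        res = run_experiment(X, subs, y, task="classification", n_folds=3,
                             seed=2, estimator_kwargs=kw)
        assert len(res.predictions) == 10
        assert set(res.predictions["subject_id"]) == set(y)

    def test_regression_with_confounds_is_leak_free(self, rng):
        n = 24
        X = rng.standard_normal((n, 20, 6))
        subs = [f"s{i}" for i in range(n)]
        age = rng.uniform(20, 40, n)
        trait = 0.5 * age + rng.standard_normal(n)
        cov = pd.DataFrame({"age": age}, index=subs)
        res = run_experiment(X, subs, dict(zip(subs, trait)), task="regression",
                             covariates=cov, n_folds=3, seed=3,
                             estimator_kwargs=_tiny_estimator() | {"max_epochs": 3})
        assert audit_leakage(res)
        assert {"pearson_r", "mae", "mae_mean", "mae_sd"} <= set(res.pooled_metrics)
        for entry in res.audit:
            assert entry["confound_fitted_on"] == entry["train_subjects"]

    def test_histories_record_both_losses(self, rng):
        n = 12
        X = rng.standard_normal((n, 20, 6))
        subs = [f"s{i}" for i in range(n)]
        y = dict(zip(subs, np.tile([0, 1], n // 2)))
        res = run_experiment(X, subs, y, task="classification", n_folds=3, seed=4,
                             estimator_kwargs=_tiny_estimator() | {"max_epochs": 3})
        for h in res.histories:
            assert len(h["train_loss"]) == len(h["val_loss"]) >= 1
            assert np.all(np.isfinite(h["train_loss"]))
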