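"""Subject-grouped cross-validation, confound regression and evaluation.

Subjects — never runs — are the unit of cross-validation: all runs of a
subject stay in the same fold, one fold is held out for testing, the next
fold in cyclic order is used for validation-based early stopping, and the
rest train the model.  For regression targets, nuisance covariates (sex,
age, mean frame-wise displacement) are regressed out of the scores with
ordinary least squares fitted on the training subjects only and applied
unchanged to validation and test subjects.

Every experiment records an audit trail (which subjects each fold's
confound fit, training and early stopping touched) so leak-freedom can be
asserted mechanically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mean_absolute_error, roc_auc_score

from .model import ChronnectomeClassifier, ChronnectomeRegressor

__all__ = [
    "FoldPlan",
    "ConfoundModel",
    "make_folds",
    "fit_confounds",
    "apply_confounds",
    "evaluate",
    "ExperimentResult",
    "run_experiment",
    "audit_leakage",
]


@dataclass
class FoldPlan:
    """Train/validation/test subject sets for each of k folds."""

    folds: list[dict[str, list[str]]]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def check_partition(self, subject_ids: list[str]) -> None:
        """Test folds must partition the subjects; val and test are disjoint."""
        all_test: list[str] = []
        for fold in self.folds:
            all_test.extend(fold["test"])
            if set(fold["test"]) & set(fold["val"]):
                raise AssertionError("validation and test overlap")
            if set(fold["test"]) & set(fold["train"]):
                raise AssertionError("train and test overlap")
            if set(fold["val"]) & set(fold["train"]):
                raise AssertionError("train and validation overlap")
        if sorted(all_test) != sorted(subject_ids):
            raise AssertionError("test folds do not partition the subjects")


def make_folds(subject_ids: list[str], k: int = 10, seed: int = 0,
               stratify_labels: dict[str, int] | None = None) -> FoldPlan:
    """Random subject-level k-fold plan with cyclic validation folds.

    For test fold ``i``, fold ``(i+1) mod k`` is the validation fold and the
    remaining k-2 folds train.  With ``stratify_labels`` the shuffle happens
    within label groups so each fold keeps the label proportions.
    """
    subject_ids = list(subject_ids)
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > len(subject_ids):
        raise ValueError(f"k={k} exceeds {len(subject_ids)} subjects")
    rng = np.random.default_rng(seed)
    if stratify_labels is None:
        order = [subject_ids[i] for i in rng.permutation(len(subject_ids))]
    else:
        order = []
        by_label: dict[int, list[str]] = {}
        for s in subject_ids:
            by_label.setdefault(stratify_labels[s], []).append(s)
        shuffled = {
            lab: [subs[i] for i in rng.permutation(len(subs))]
            for lab, subs in sorted(by_label.items())
        }
        # interleave so array_split keeps proportions
        pools = list(shuffled.values())
        while any(pools):
            for pool in pools:
                if pool:
                    order.append(pool.pop())
    chunks = [c.tolist() for c in np.array_split(np.array(order, dtype=object), k)]
    folds = []
    for i in range(k):
        val = chunks[(i + 1) % k]
        train = [s for j, c in enumerate(chunks) if j not in (i, (i + 1) % k)
                 for s in c]
        folds.append({"train": train, "val": list(val), "test": list(chunks[i])})
    plan = FoldPlan(folds=folds, seed=seed)
    plan.check_partition(subject_ids)
    return plan


@dataclass
class ConfoundModel:
    """OLS nuisance model for a continuous target, fitted on training subjects."""

    covariate_names: list[str]
    coef: np.ndarray
    intercept: float
    fitted_on: list[str] = field(default_factory=list)

    def residualize(self, scores: np.ndarray, covariates: np.ndarray) -> np.ndarray:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        return np.asarray(scores, dtype=float) - (
            self.intercept + covariates @ self.coef
        )


def fit_confounds(train_scores: np.ndarray, train_covariates: np.ndarray,
                  covariate_names: list[str] | None = None,
                  fitted_on: list[str] | None = None) -> ConfoundModel:
    """Ordinary least squares of scores on covariates (with intercept)."""
    y = np.asarray(train_scores, dtype=float)
    x = np.atleast_2d(np.asarray(train_covariates, dtype=float))
    if x.shape[0] != y.shape[0]:
        raise ValueError("scores and covariates length mismatch")
    design = np.column_stack([np.ones(len(y)), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient confound design matrix")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    names = covariate_names or [f"cov{i}" for i in range(x.shape[1])]
    return ConfoundModel(
        covariate_names=list(names),
        coef=beta[1:],
        intercept=float(beta[0]),
        fitted_on=list(fitted_on or []),
    )


def apply_confounds(model: ConfoundModel, scores: np.ndarray,
                    covariates: np.ndarray) -> np.ndarray:
    """Residual scores under a previously fitted confound model."""
    return model.residualize(scores, covariates)


def evaluate(y_true: np.ndarray, y_pred: np.ndarray, task: str,
             y_score: np.ndarray | None = None) -> dict[str, float]:
    """Task metrics: accuracy + AUC (classification), Pearson r + MAE (regression)."""
    import warnings

    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape[0] != y_pred.shape[0]:
        raise ValueError("prediction/truth length mismatch")
    if task == "classification":
        acc = float(np.mean(y_true == y_pred))
        score = y_score if y_score is not None else y_pred
        if len(np.unique(y_true)) < 2:
            auc = np.nan
        else:
            auc = float(roc_auc_score(y_true, score))
        return {"accuracy": acc, "auc": auc}
    if task == "regression":
        if np.std(y_pred) == 0 or np.std(y_true) == 0:
            warnings.warn("constant predictions or truth: Pearson r reported as 0",
                          UserWarning, stacklevel=2)
            r = 0.0
        else:
            r = float(stats.pearsonr(y_true, y_pred)[0])
        return {"pearson_r": r, "mae": float(mean_absolute_error(y_true, y_pred))}
    raise ValueError(f"unknown task {task!r}")


@dataclass
class ExperimentResult:
    """Cross-validated report: per-fold metrics, pooled metrics, predictions."""

    task: str
    fold_metrics: list[dict[str, float]]
    pooled_metrics: dict[str, float]
    predictions: pd.DataFrame
    histories: list[dict]
    audit: list[dict]
    plan: FoldPlan


def _subject_aggregate(run_values: np.ndarray, run_subjects: list[str],
                       subjects: list[str]) -> np.ndarray:
    """Mean of per-run predictions over each subject's runs."""
    run_subjects = np.asarray(run_subjects)
    out = []
    for s in subjects:
        mask = run_subjects == s
        out.append(run_values[mask].mean(axis=0))
    return np.asarray(out)


def run_experiment(
    Z: np.ndarray,
    run_subjects: list[str],
    targets: dict[str, float],
    task: str = "classification",
    covariates: pd.DataFrame | None = None,
    n_folds: int = 10,
    seed: int = 0,
    estimator_kwargs: dict | None = None,
    stratify: bool = False,
) -> ExperimentResult:
    """Full subject-grouped cross-validated experiment on dFC sequences.

    ``Z`` is the stacked dFC input ``(n_runs, W, E)``; ``run_subjects`` maps
    each run to its subject; ``targets`` maps subjects to the class label or
    continuous score.  For regression, ``covariates`` (indexed by subject)
    are regressed out of the scores per fold, coefficients fitted on the
    training subjects only.  Test predictions of a subject's runs are
    averaged into one subject-level prediction.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 3:
        raise ValueError("Z must be (n_runs, n_windows, n_edges)")
    if Z.shape[0] != len(run_subjects):
        raise ValueError("run_subjects length mismatch")
    run_subjects = [str(s) for s in run_subjects]
    subjects = sorted(set(run_subjects))
    missing = [s for s in subjects if s not in targets]
    if missing:
        raise ValueError(f"targets missing for subjects: {missing[:5]}")
    estimator_kwargs = dict(estimator_kwargs or {})
    rng = np.random.default_rng(seed)
    strat = ({s: int(targets[s]) for s in subjects}
             if (stratify and task == "classification") else None)
    plan = make_folds(subjects, k=n_folds, seed=int(rng.integers(2**31 - 1)),
                      stratify_labels=strat)

    run_subj_arr = np.asarray(run_subjects)

    def runs_of(subject_set):
        return np.flatnonzero(np.isin(run_subj_arr, list(subject_set)))

    fold_metrics = []
    histories = []
    audit = []
    pred_rows = []
    for fold_id, fold in enumerate(plan.folds):
        tr_idx, va_idx, te_idx = (runs_of(fold[part]) for part in ("train", "val", "test"))
        if len(tr_idx) == 0 or len(te_idx) == 0:
            raise RuntimeError(f"fold {fold_id}: empty train or test set")

        y_by_subject = {s: targets[s] for s in subjects}
        confound = None
        if task == "regression" and covariates is not None:
            cov = covariates.loc[fold["train"]].to_numpy(dtype=float)
            confound = fit_confounds(
                np.array([y_by_subject[s] for s in fold["train"]], dtype=float),
                cov,
                covariate_names=list(covariates.columns),
                fitted_on=list(fold["train"]),
            )

            def target_of(subject_list):
                raw = np.array([y_by_subject[s] for s in subject_list], dtype=float)
                return apply_confounds(
                    confound, raw, covariates.loc[subject_list].to_numpy(dtype=float)
                )
        else:

            def target_of(subject_list):
                return np.array([y_by_subject[s] for s in subject_list])

        def run_targets(idx, subject_list):
            per_subject = dict(zip(subject_list, target_of(subject_list)))
            return np.array([per_subject[run_subjects[i]] for i in idx])

        fold_seed = int(rng.integers(2**31 - 1))
        cls = ChronnectomeClassifier if task == "classification" else ChronnectomeRegressor
        est = cls(random_state=fold_seed, **estimator_kwargs)
        est.fit(
            Z[tr_idx],
            run_targets(tr_idx, fold["train"]),
            X_val=Z[va_idx] if len(va_idx) else None,
            y_val=run_targets(va_idx, fold["val"]) if len(va_idx) else None,
        )
        histories.append(est.history_)

        test_subjects = [s for s in fold["test"] if np.any(run_subj_arr == s)]
        y_true = target_of(test_subjects)
        if task == "classification":
            proba_runs = est.predict_proba(Z[te_idx])
            proba = _subject_aggregate(proba_runs, [run_subjects[i] for i in te_idx],
                                       test_subjects)
            y_pred = est.classes_[proba.argmax(axis=1)]
            y_score = proba[:, 1]
            metrics = evaluate(y_true, y_pred, task, y_score=y_score)
            for s, yt, yp, sc in zip(test_subjects, y_true, y_pred, y_score):
                pred_rows.append({"subject_id": s, "fold": fold_id, "y_true": yt,
                                  "y_pred": yp, "score": sc})
        else:
            pred_runs = est.predict(Z[te_idx])[:, None]
            y_pred = _subject_aggregate(pred_runs, [run_subjects[i] for i in te_idx],
                                        test_subjects)[:, 0]
            metrics = evaluate(y_true, y_pred, task)
            for s, yt, yp in zip(test_subjects, y_true, y_pred):
                pred_rows.append({"subject_id": s, "fold": fold_id, "y_true": yt,
                                  "y_pred": yp, "score": yp})
        fold_metrics.append(metrics)
        audit.append(
            {
                "fold": fold_id,
                "train_subjects": sorted(fold["train"]),
                "val_subjects": sorted(fold["val"]),
                "test_subjects": sorted(fold["test"]),
                "confound_fitted_on": sorted(confound.fitted_on) if confound else [],
                "early_stop_monitored": sorted(fold["val"]),
            }
        )

    predictions = pd.DataFrame(pred_rows)
    if task == "classification":
        pooled = evaluate(
            predictions["y_true"].to_numpy(),
            predictions["y_pred"].to_numpy(),
            task,
            y_score=predictions["score"].to_numpy(),
        )
    else:
        pooled = evaluate(
            predictions["y_true"].to_numpy(),
            predictions["y_pred"].to_numpy(),
            task,
        )
        per_fold_mae = [m["mae"] for m in fold_metrics]
        pooled["mae_mean"] = float(np.mean(per_fold_mae))
        pooled["mae_sd"] = float(np.std(per_fold_mae, ddof=1)) if len(per_fold_mae) > 1 else 0.0
    return ExperimentResult(
        task=task,
        fold_metrics=fold_metrics,
        pooled_metrics=pooled,
        predictions=predictions,
        histories=histories,
        audit=audit,
        plan=plan,
    )


#: desk-scale training configuration for the synthetic-cohort experiments:
#: constant Adam rate, small batches (many updates per epoch on a
#: 100-200-run training fold) and patient early stopping
DESK_SCALE_ESTIMATOR = {
    "learning_rate": 1e-3,
    "lr_decay": 1.0,
    "batch_size": 16,
    "max_epochs": 50,
    "patience": 10,
    # an epoch must beat the best validation loss by this margin to be
    # checkpointed: chance dips on an unlearnable (e.g. surrogate) problem
    # must not select overfit weights
    "min_delta": 0.02,
}

#: desk-scale dFC extraction: 20-sample windows (14.4 s at TR = 0.72 s)
#: resolve the slow class's regimes at T = 300; per-edge centering removes
#: the class-matched static baseline so the network sees fluctuations
DESK_SCALE_DFC = {
    "window_samples": 20,
    "stride_samples": 5,
    "edge_normalization": "center",
}


def dynamics_classification_pipeline(
    window_samples: int = 20,
    stride_samples: int = 5,
    tr_seconds: float = 0.72,
    edge_normalization: str | None = "center",
    n_folds: int = 5,
    estimator_kwargs: dict | None = None,
    stratify: bool = True,
):
    """Callable running the full raw-signals -> dFC -> CV pipeline.

    Returns ``pipeline(X_runs, run_subjects, targets, seed) -> accuracy``;
    the same callable serves the real data and the MVPR surrogate copies in
    :func:`deepchronnect.surrogate.null_accuracy_distribution`, so the
    comparison is between identical pipelines.
    """
    from .dfc import SlidingWindowConnectivity

    kwargs = dict(DESK_SCALE_ESTIMATOR)
    kwargs.update(estimator_kwargs or {})

    def pipeline(X_runs, run_subjects, targets, seed):
        sw = SlidingWindowConnectivity(
            window_samples, stride_samples, tr_seconds,
            edge_normalization=edge_normalization,
        )
        Z = sw.fit_transform(np.asarray(X_runs, dtype=float))
        result = run_experiment(
            Z, run_subjects, targets, task="classification",
            n_folds=n_folds, seed=seed, estimator_kwargs=kwargs,
            stratify=stratify,
        )
        return float(result.pooled_metrics["accuracy"])

    return pipeline


def audit_leakage(result: ExperimentResult) -> bool:
    """Assert that no fold's confound fit or early stopping saw test subjects."""
    for entry in result.audit:
        test = set(entry["test_subjects"])
        if set(entry["confound_fitted_on"]) & test:
            raise AssertionError(f"fold {entry['fold']}: confounds fitted on test subjects")
        if set(entry["early_stop_monitored"]) & test:
            raise AssertionError(f"fold {entry['fold']}: early stopping saw test subjects")
        if set(entry["train_subjects"]) & test:
            raise AssertionError(f"fold {entry['fold']}: training saw test subjects")
    result.plan.check_partition(
        sorted({s for e in result.audit for s in e["test_subjects"]})
    )
    return True
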