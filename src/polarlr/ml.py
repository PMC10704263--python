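"""Patient-grouped cross-validated classification of local-recurrence status.

The workflow mirrors a clinical ROI-level study with a single label per
patient: folds are formed over *patients* (never splitting a patient's ROIs
across train and test), five off-the-shelf learners are trained on ROI
feature vectors, ROI predictions are aggregated to a patient call by
majority vote at a 50% threshold, and performance is reported fold-wise as
mean ± SD sensitivity, specificity, accuracy (ROI and patient level) and
AUROC, with a vertically averaged mean ROC curve.

Feature selection ranks min-max-normalized importances across learners;
outlier elimination greedily drops whole patients whose removal improves
cross-validated AUROC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc, roc_curve
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .decomposition import FEATURE_NAMES

__all__ = [
    "MODEL_NAMES",
    "SplitPlan",
    "FoldResult",
    "PerformanceReport",
    "FeatureImportanceTable",
    "grouped_kfold",
    "make_model",
    "train_models",
    "FittedModel",
    "majority_vote",
    "performance_metrics",
    "roc_and_auroc",
    "mean_roc",
    "rank_features",
    "eliminate_outliers",
    "run_experiment",
    "run_full_workflow",
]

MODEL_NAMES = ("logistic", "lda", "svm", "random_forest", "xgboost")

_FPR_GRID = np.linspace(0.0, 1.0, 101)


# ---------------------------------------------------------------------------
# split plan


@dataclass(frozen=True)
class SplitPlan:
    """k disjoint patient-level folds; fold i tests on ``folds[i]``."""

    folds: tuple[tuple[str, ...], ...]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def train_test(self, i: int) -> tuple[tuple[str, ...], tuple[str, ...]]:
        test = self.folds[i]
        train = tuple(p for j, f in enumerate(self.folds) if j != i for p in f)
        return train, test

    def validate(self) -> None:
        all_pids = [p for f in self.folds for p in f]
        if len(all_pids) != len(set(all_pids)):
            raise AssertionError("patient appears in more than one test fold")
        for i in range(self.k):
            train, test = self.train_test(i)
            if set(train) & set(test):
                raise AssertionError(f"train/test leakage in fold {i}")


def grouped_kfold(patient_labels: Mapping[str, int], k: int, seed: int) -> SplitPlan:
    """Stratified patient-level k-fold plan.

    Patients (groups) are assigned whole to folds; within each label class
    patients are shuffled and chunked, and each class's larger chunks go to
    the folds currently smallest so fold sizes differ by at most one patient
    while keeping the label mix as even as the counts allow.
    """
    pids = sorted(patient_labels)
    if k > len(pids):
        raise ValueError(f"k={k} exceeds number of patients ({len(pids)})")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    labels = sorted(set(patient_labels.values()))
    # larger classes first so the smaller class can rebalance totals
    classes = sorted(labels, key=lambda c: (-sum(patient_labels[p] == c for p in pids), c))
    for c in classes:
        members = [p for p in pids if patient_labels[p] == c]
        rng.shuffle(members)
        base, extra = divmod(len(members), k)
        sizes = [base + 1] * extra + [base] * (k - extra)
        order = np.argsort([len(f) for f in folds], kind="stable")
        pos = 0
        for size, fi in zip(sizes, order):
            folds[fi].extend(members[pos : pos + size])
            pos += size
    plan = SplitPlan(tuple(tuple(sorted(f)) for f in folds), seed)
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# models


def make_model(name: str, seed: int = 0):
    """Instantiate one of the five supported learners with library defaults.

    Linear models are standardized; tree ensembles are not.  No tuning loop.
    """
    if name == "logistic":
        return Pipeline(
            [("scale", StandardScaler()), ("clf", LogisticRegression(max_iter=2000))]
        )
    if name == "lda":
        return Pipeline(
            [("scale", StandardScaler()), ("clf", LinearDiscriminantAnalysis())]
        )
    if name == "svm":
        return Pipeline(
            [("scale", StandardScaler()), ("clf", SVC(kernel="linear", random_state=seed))]
        )
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if name == "xgboost":
        return XGBClassifier(
            random_state=seed,
            n_jobs=1,
            importance_type="gain",
            eval_metric="logloss",
            verbosity=0,
        )
    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


@dataclass
class FittedModel:
    """Uniform adapter over a fitted learner: scores, labels, raw importances."""

    name: str
    estimator: object
    feature_names: tuple[str, ...]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(X))

    def scores(self, X: np.ndarray) -> np.ndarray:
        est = self.estimator
        if hasattr(est, "predict_proba"):
            try:
                return np.asarray(est.predict_proba(X))[:, 1]
            except AttributeError:  # pragma: no cover
                pass
        return np.asarray(est.decision_function(X))

    def importances(self) -> np.ndarray:
        est = self.estimator
        if isinstance(est, Pipeline):
            est = est[-1]
        if hasattr(est, "feature_importances_"):
            imp = np.asarray(est.feature_importances_, dtype=float)
        elif hasattr(est, "coef_"):
            imp = np.abs(np.asarray(est.coef_, dtype=float)).ravel()
        else:  # pragma: no cover
            raise AttributeError(f"model {self.name} exposes no importances")
        if imp.shape != (len(self.feature_names),):
            raise AssertionError(
                f"importance length {imp.shape} != n_features {len(self.feature_names)}"
            )
        return imp


def train_models(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    model_names: Sequence[str] = MODEL_NAMES,
    seed: int = 0,
) -> dict[str, FittedModel]:
    """Fit the requested learners on one training set."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError(
            f"training data contains a single class ({np.unique(y)}); "
            "cannot fit a binary classifier"
        )
    fitted = {}
    for name in model_names:
        est = make_model(name, seed=seed)
        est.fit(X, y)
        fitted[name] = FittedModel(name, est, tuple(feature_names))
    return fitted


# ---------------------------------------------------------------------------
# metrics


def majority_vote(roi_predictions: Sequence[int], threshold: float = 0.5) -> int:
    """Patient call from ROI calls: LR (1) iff the LR fraction is >= threshold.

    An exact tie at the 50% threshold resolves to the positive (LR) class —
    the clinically conservative reading of "50% or more".
    """
    preds = np.asarray(roi_predictions)
    if preds.size == 0:
        raise ValueError("majority_vote requires at least one ROI prediction")
    return int(np.mean(preds == 1) >= threshold)


def confusion_2x2(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """2×2 confusion matrix [[TN, FP], [FN, TP]]."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    return np.array([[tn, fp], [fn, tp]], dtype=float)


def performance_metrics(cm: np.ndarray) -> dict:
    """Sensitivity, specificity and total accuracy from [[TN, FP], [FN, TP]].

    Zero-denominator ratios come back as NaN together with a flag naming the
    undefined metric, never as a silent exception.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.shape != (2, 2) or np.any(cm < 0):
        raise ValueError(f"confusion matrix must be 2x2 non-negative, got {cm}")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zero")
    (tn, fp), (fn, tp) = cm
    flags = []
    if tp + fn > 0:
        sens = tp / (tp + fn)
    else:
        sens, flags = np.nan, flags + ["sensitivity_undefined"]
    if tn + fp > 0:
        spec = tn / (tn + fp)
    else:
        spec, flags = np.nan, flags + ["specificity_undefined"]
    return {
        "sensitivity": float(sens),
        "specificity": float(spec),
        "accuracy": float((tp + tn) / total),
        "flags": flags,
    }


def roc_and_auroc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points and AUROC (tie-corrected; equals the normalized Mann–Whitney U)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes in the labels")
    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr, float(auc(fpr, tpr))


def mean_roc(
    curves: Sequence[tuple[np.ndarray, np.ndarray]], aurocs: Sequence[float]
) -> dict:
    """Vertical averaging of fold ROC curves on a fixed 101-point FPR grid."""
    tprs = []
    for fpr, tpr in curves:
        interp = np.interp(_FPR_GRID, fpr, tpr)
        interp[0] = 0.0
        tprs.append(interp)
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[-1] = 1.0
    return {
        "fpr": _FPR_GRID.copy(),
        "tpr": mean_tpr,
        "auroc_mean": float(np.mean(aurocs)),
        "auroc_sd": float(np.std(aurocs)),
    }


# ---------------------------------------------------------------------------
# feature ranking


@dataclass
class FeatureImportanceTable:
    """Raw and min-max-normalized importances per model, plus the aggregate ranking."""

    raw: pd.DataFrame  # models × features
    normalized: pd.DataFrame
    aggregate: pd.Series
    selected: list[str]
    flags: list[str] = field(default_factory=list)


def rank_features(
    importances: Mapping[str, np.ndarray],
    feature_names: Sequence[str],
    k: int = 5,
) -> FeatureImportanceTable:
    """Aggregate per-model importances into one ranking and select the top k.

    Each model's vector is min-max normalized to [0, 1]; the aggregate is the
    mean normalized importance across models; ties break deterministically by
    feature name.  A constant importance vector normalizes to zeros (flagged).
    """
    if not importances:
        raise ValueError("rank_features requires at least one model importance vector")
    raw = pd.DataFrame(
        {m: np.asarray(v, dtype=float) for m, v in importances.items()},
        index=list(feature_names),
    ).T
    flags = []
    norm = {}
    for m, row in raw.iterrows():
        lo, hi = row.min(), row.max()
        if hi > lo:
            norm[m] = (row - lo) / (hi - lo)
        else:
            norm[m] = row * 0.0
            flags.append(f"constant_importances:{m}")
    norm_df = pd.DataFrame(norm).T
    aggregate = norm_df.mean(axis=0)
    order = sorted(aggregate.index, key=lambda n: (-aggregate[n], n))
    return FeatureImportanceTable(
        raw=raw,
        normalized=norm_df,
        aggregate=aggregate,
        selected=order[:k],
        flags=flags,
    )


# ---------------------------------------------------------------------------
# experiment driver


@dataclass
class FoldResult:
    """Everything measured on one test fold for one model."""

    model: str
    fold: int
    roi_true: np.ndarray
    roi_pred: np.ndarray
    roi_scores: np.ndarray
    patient_ids: tuple[str, ...]
    patient_true: np.ndarray
    patient_pred: np.ndarray
    cm_roi: np.ndarray
    cm_patient: np.ndarray
    roc: tuple[np.ndarray, np.ndarray] | None
    auroc: float
    importances: np.ndarray


@dataclass
class PerformanceReport:
    """Fold-averaged metrics for one model (ROI and patient level)."""

    model: str
    n_folds: int
    roi: dict
    patient: dict
    auroc_mean: float
    auroc_sd: float
    mean_roc: dict
    mean_cm_roi: np.ndarray
    mean_cm_patient: np.ndarray
    folds: list[FoldResult]
    importances_mean: np.ndarray

    def summary(self) -> dict:
        return {
            "model": self.model,
            "roi": self.roi,
            "patient": self.patient,
            "auroc_mean": self.auroc_mean,
            "auroc_sd": self.auroc_sd,
        }


def _check_cohort(df: pd.DataFrame, feature_names: Sequence[str]) -> None:
    required = {"patient_id", "roi_id", "label", *feature_names}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    per_pat = df.groupby("patient_id")["label"].nunique()
    if (per_pat > 1).any():
        bad = per_pat[per_pat > 1].index.tolist()
        raise ValueError(f"patients with inconsistent ROI labels: {bad}")


def _evaluate_fold(
    df: pd.DataFrame,
    train_pids: Iterable[str],
    test_pids: Iterable[str],
    model_name: str,
    feature_names: Sequence[str],
    fold_index: int,
    seed: int,
    vote_threshold: float,
) -> FoldResult:
    train = df[df["patient_id"].isin(set(train_pids))]
    test = df[df["patient_id"].isin(set(test_pids))]
    Xtr = train[list(feature_names)].to_numpy()
    ytr = train["label"].to_numpy()
    Xte = test[list(feature_names)].to_numpy()
    yte = test["label"].to_numpy()
    fitted = train_models(Xtr, ytr, feature_names, [model_name], seed=seed)[model_name]
    pred = fitted.predict(Xte).astype(int)
    scores = fitted.scores(Xte)

    pids, ptrue, ppred = [], [], []
    for pid, grp in test.groupby("patient_id", sort=True):
        idx = grp.index
        pids.append(pid)
        ptrue.append(int(grp["label"].iloc[0]))
        ppred.append(majority_vote(pred[test.index.get_indexer(idx)], vote_threshold))

    if len(np.unique(yte)) == 2:
        fpr, tpr, auroc = roc_and_auroc(scores, yte)
        roc = (fpr, tpr)
    else:
        roc, auroc = None, np.nan
    return FoldResult(
        model=model_name,
        fold=fold_index,
        roi_true=yte,
        roi_pred=pred,
        roi_scores=scores,
        patient_ids=tuple(pids),
        patient_true=np.array(ptrue),
        patient_pred=np.array(ppred),
        cm_roi=confusion_2x2(yte, pred),
        cm_patient=confusion_2x2(np.array(ptrue), np.array(ppred)),
        roc=roc,
        auroc=auroc,
        importances=fitted.importances(),
    )


def _aggregate(model: str, folds: list[FoldResult]) -> PerformanceReport:
    def stat(values: list[float]) -> dict:
        arr = np.asarray(values, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return {"mean": float(np.nanmean(arr)), "sd": float(np.nanstd(arr))}

    roi_m = [performance_metrics(f.cm_roi) for f in folds]
    pat_m = [performance_metrics(f.cm_patient) for f in folds]
    curves = [f.roc for f in folds if f.roc is not None]
    aurocs = [f.auroc for f in folds if np.isfinite(f.auroc)]
    mroc = mean_roc(curves, aurocs) if curves else {"fpr": _FPR_GRID.copy(), "tpr": np.full(101, np.nan), "auroc_mean": np.nan, "auroc_sd": np.nan}
    return PerformanceReport(
        model=model,
        n_folds=len(folds),
        roi={
            "sensitivity": stat([m["sensitivity"] for m in roi_m]),
            "specificity": stat([m["specificity"] for m in roi_m]),
            "accuracy": stat([m["accuracy"] for m in roi_m]),
        },
        patient={
            "sensitivity": stat([m["sensitivity"] for m in pat_m]),
            "specificity": stat([m["specificity"] for m in pat_m]),
            "accuracy": stat([m["accuracy"] for m in pat_m]),
        },
        auroc_mean=mroc["auroc_mean"],
        auroc_sd=mroc["auroc_sd"],
        mean_roc=mroc,
        mean_cm_roi=np.mean([f.cm_roi for f in folds], axis=0),
        mean_cm_patient=np.mean([f.cm_patient for f in folds], axis=0),
        folds=folds,
        importances_mean=np.mean([f.importances for f in folds], axis=0),
    )


def run_experiment(
    df: pd.DataFrame,
    model_names: Sequence[str] = MODEL_NAMES,
    feature_names: Sequence[str] | None = None,
    k: int = 5,
    seed: int = 0,
    vote_threshold: float = 0.5,
) -> dict[str, PerformanceReport]:
    """Grouped k-fold cross-validation of the requested models on a cohort table.

    ``df`` carries one row per ROI (patient_id, roi_id, label + features).
    Fully reproducible for a given seed.
    """
    feature_names = list(feature_names or FEATURE_NAMES)
    _check_cohort(df, feature_names)
    df = df.reset_index(drop=True)
    labels = df.groupby("patient_id")["label"].first().to_dict()
    if len(set(labels.values())) < 2:
        raise ValueError("cohort contains a single class")
    plan = grouped_kfold(labels, k, seed)
    reports = {}
    for name in model_names:
        folds = [
            _evaluate_fold(df, *plan.train_test(i), name, feature_names, i, seed, vote_threshold)
            for i in range(k)
        ]
        reports[name] = _aggregate(name, folds)
    return reports


def _cv_auroc(
    df: pd.DataFrame,
    model_name: str,
    feature_names: Sequence[str],
    k: int,
    seed: int,
    plan: SplitPlan | None = None,
) -> float:
    """Pooled out-of-fold ROI-level AUROC.

    When ``plan`` is given, its patient partition is reused with absent
    patients filtered out, so candidate-removal comparisons are not confounded
    by fold reshuffling.
    """
    labels = df.groupby("patient_id")["label"].first().to_dict()
    if plan is None:
        plan = grouped_kfold(labels, k, seed)
    present = set(df["patient_id"])
    scores, ys = [], []
    for i in range(plan.k):
        train_p, test_p = plan.train_test(i)
        train_p = [p for p in train_p if p in present]
        test_p = [p for p in test_p if p in present]
        if not test_p or len({labels[p] for p in train_p}) < 2:
            continue
        fr = _evaluate_fold(df, train_p, test_p, model_name, feature_names, i, seed, 0.5)
        scores.append(fr.roi_scores)
        ys.append(fr.roi_true)
    if not scores:
        raise ValueError("no evaluable fold (empty test sets or single-class training)")
    _, _, auroc = roc_and_auroc(np.concatenate(scores), np.concatenate(ys))
    return auroc


def eliminate_outliers(
    df: pd.DataFrame,
    model_name: str = "xgboost",
    budget: int = 3,
    tol: float = 0.005,
    k: int = 5,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
    n_repeats: int = 3,
) -> tuple[pd.DataFrame, list[dict]]:
    """Greedy leave-one-patient-out elimination of performance-degrading patients.

    Each round evaluates, for every remaining patient, the cross-validated
    AUROC of the cohort with that patient held out entirely; the patient whose
    removal improves AUROC the most is dropped if the improvement exceeds
    ``tol``.  Stops at ``budget`` removals or when no removal helps.  Returns
    the reduced cohort and a log of removals with before/after AUROC.

    The CV score is the pooled out-of-fold AUROC averaged over ``n_repeats``
    fixed patient partitions (repeated grouped CV); fixing the partitions
    across candidates keeps comparisons free of fold-reshuffle noise, and
    averaging over several partitions keeps a single unlucky partition from
    driving removals.
    """
    feature_names = list(feature_names or FEATURE_NAMES)
    _check_cohort(df, feature_names)
    n_pat = df["patient_id"].nunique()
    if n_pat - budget < 2 * k:
        raise ValueError(
            f"budget {budget} infeasible: {n_pat} patients minus budget must "
            f"leave at least {2 * k}"
        )
    current = df.reset_index(drop=True)
    log: list[dict] = []
    labels = current.groupby("patient_id")["label"].first().to_dict()
    plans = [grouped_kfold(labels, k, seed + 9973 * j) for j in range(n_repeats)]

    def score_of(frame: pd.DataFrame) -> float:
        return float(
            np.mean(
                [_cv_auroc(frame, model_name, feature_names, k, seed, plan=p) for p in plans]
            )
        )

    baseline = score_of(current)
    for _ in range(budget):
        candidates = sorted(current["patient_id"].unique())
        best_pid, best_auroc = None, baseline
        for pid in candidates:
            reduced = current[current["patient_id"] != pid]
            if reduced.groupby("patient_id")["label"].first().nunique() < 2:
                continue
            try:
                score = score_of(reduced)
            except ValueError:
                continue
            if score > best_auroc + 1e-12 and (best_pid is None or score > best_auroc):
                best_pid, best_auroc = pid, score
        if best_pid is None or best_auroc - baseline <= tol:
            break
        log.append(
            {"patient_id": best_pid, "auroc_before": baseline, "auroc_after": best_auroc}
        )
        current = current[current["patient_id"] != best_pid].reset_index(drop=True)
        baseline = best_auroc
    return current, log


def run_full_workflow(
    df: pd.DataFrame,
    model_names: Sequence[str] = MODEL_NAMES,
    k: int = 5,
    seed: int = 0,
    top_k: int = 5,
    vote_threshold: float = 0.5,
    outlier_budget: int = 0,
    outlier_tol: float = 0.005,
    outlier_model: str = "xgboost",
    t_stage: pd.Series | Mapping[str, int] | None = None,
    t_stage_subgroup: int | None = 3,
) -> dict:
    """The full study workflow on one cohort table.

    Optional outlier elimination, then an all-features experiment, cross-model
    feature ranking, a top-k-features experiment, and (when a T-stage mapping
    is supplied) a top-k experiment restricted to the T-stage subgroup.
    """
    result: dict = {"seed": seed, "k": k}
    removal_log: list[dict] = []
    if outlier_budget > 0:
        df, removal_log = eliminate_outliers(
            df, outlier_model, outlier_budget, outlier_tol, k, seed
        )
    result["removal_log"] = removal_log

    all_feat = run_experiment(df, model_names, FEATURE_NAMES, k, seed, vote_threshold)
    result["all_features"] = all_feat

    table = rank_features(
        {m: r.importances_mean for m, r in all_feat.items()}, FEATURE_NAMES, k=top_k
    )
    result["importance_table"] = table

    top = run_experiment(df, model_names, table.selected, k, seed, vote_threshold)
    result["top_features"] = top

    if t_stage is not None and t_stage_subgroup is not None:
        ts = dict(t_stage)
        sub = df[df["patient_id"].map(ts) == t_stage_subgroup]
        n_pat = sub["patient_id"].nunique()
        n_classes = sub.groupby("patient_id")["label"].first().nunique()
        if n_pat < k or n_classes < 2:
            raise ValueError(
                f"T-stage {t_stage_subgroup} subgroup has {n_pat} patients / "
                f"{n_classes} classes; cannot run {k}-fold CV"
            )
        result["top_features_subgroup"] = run_experiment(
            sub, model_names, table.selected, k, seed, vote_threshold
        )
    return result
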