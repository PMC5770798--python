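"""Evaluation protocol: confusion metrics, ROC/PR areas, cross-validation,
balanced resampling and one-vs-rest family evaluation.

Threshold metrics follow the standard definitions: sensitivity
tp/(tp+fn), specificity tn/(tn+fp), accuracy (tp+tn)/total, precision
tp/(tp+fp) and Matthews correlation coefficient
(tp*tn - fp*fn) / sqrt((tp+fn)(tp+fp)(tn+fn)(tn+fp)).
A zero denominator yields NaN rather than a silent zero, so undefined
folds do not distort averages. AUC-ROC is trapezoidal over all score
thresholds (equivalently the fraction of correctly ordered
positive/negative pairs, ties counted one half); AUC-PR uses the
step-wise average-precision rule.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import KFold, LeaveOneOut, StratifiedKFold

METRIC_FIELDS = (
    "sensitivity",
    "specificity",
    "accuracy",
    "precision",
    "mcc",
    "auc_roc",
    "auc_pr",
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    sensitivity: float = math.nan
    specificity: float = math.nan
    accuracy: float = math.nan
    precision: float = math.nan
    mcc: float = math.nan
    auc_roc: float = math.nan
    auc_pr: float = math.nan
    se: dict[str, float] | None = None

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in METRIC_FIELDS}
        if self.se is not None:
            d["se"] = dict(self.se)
        return d


def confusion(y_true, y_pred, pos_label) -> ConfusionCounts:
    """Exact confusion counts for a designated positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape[0]} true vs {y_pred.shape[0]} predicted"
        )
    tp = int(np.sum((y_true == pos_label) & (y_pred == pos_label)))
    fn = int(np.sum((y_true == pos_label) & (y_pred != pos_label)))
    fp = int(np.sum((y_true != pos_label) & (y_pred == pos_label)))
    tn = int(np.sum((y_true != pos_label) & (y_pred != pos_label)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def metrics(cc: ConfusionCounts) -> MetricsReport:
    """The five threshold metrics from confusion counts (AUCs left NaN)."""
    tp, tn, fp, fn = cc.tp, cc.tn, cc.fp, cc.fn
    mcc_den = math.sqrt(
        float(tp + fn) * float(tp + fp) * float(tn + fn) * float(tn + fp)
    )
    return MetricsReport(
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        accuracy=_ratio(tp + tn, cc.total),
        precision=_ratio(tp, tp + fp),
        mcc=(tp * tn - fp * fn) / mcc_den if mcc_den > 0 else math.nan,
    )


def _binary_indicator(y_true, pos_label) -> np.ndarray:
    y_true = np.asarray(y_true)
    ind = (y_true == pos_label).astype(int)
    return ind


def roc_points(scores, y_true, pos_label=1) -> tuple[np.ndarray, np.ndarray]:
    """(fpr, tpr) over all score thresholds."""
    ind = _binary_indicator(y_true, pos_label)
    if ind.min() == ind.max():
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(ind, scores, drop_intermediate=False)
    return fpr, tpr


def auc_roc(scores, y_true, pos_label=1) -> float:
    """Area under the ROC curve; equals the probability a random positive
    outscores a random negative, ties counted one half."""
    ind = _binary_indicator(y_true, pos_label)
    if ind.min() == ind.max():
        raise ValueError("AUC-ROC requires both classes present")
    return float(roc_auc_score(ind, scores))


def pr_points(scores, y_true, pos_label=1) -> tuple[np.ndarray, np.ndarray]:
    """(recall, precision) over all score thresholds."""
    ind = _binary_indicator(y_true, pos_label)
    if ind.sum() == 0:
        raise ValueError("PR curve requires at least one positive")
    precision, recall, _ = precision_recall_curve(ind, scores)
    return recall, precision


def auc_pr(scores, y_true, pos_label=1) -> float:
    """Area under the precision-recall curve (average precision)."""
    ind = _binary_indicator(y_true, pos_label)
    if ind.sum() == 0:
        raise ValueError("AUC-PR requires at least one positive")
    return float(average_precision_score(ind, scores))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVPlan:
    """Cross-validation scheme: stratified k-fold (default 5) or LOOCV."""

    scheme: str = "kfold"
    k: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("kfold", "loocv"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "kfold" and self.k < 2:
            raise ValueError("kfold requires k >= 2")

    def splitter(self):
        if self.scheme == "loocv":
            return LeaveOneOut()
        if self.stratified:
            return StratifiedKFold(n_splits=self.k, shuffle=True, random_state=self.seed)
        return KFold(n_splits=self.k, shuffle=True, random_state=self.seed)


@dataclass
class CVResult:
    fold_reports: list[MetricsReport]
    mean: MetricsReport
    assignments: list[np.ndarray]  # test indices per fold

    @property
    def pooled(self) -> bool:
        return len(self.fold_reports) == 0


def _evaluate_split(model, X_test, y_test, pos_label) -> tuple[np.ndarray, np.ndarray | None]:
    y_pred = model.predict(X_test)
    scores = None
    if pos_label is not None and hasattr(model, "predict_proba"):
        proba = model.predict_proba(X_test)
        classes = list(model.classes_)
        scores = np.asarray(proba)[:, classes.index(pos_label)]
    return np.asarray(y_pred), scores


def _binary_report(y_true, y_pred, scores, pos_label) -> MetricsReport:
    report = metrics(confusion(y_true, y_pred, pos_label))
    if scores is not None and len(np.unique(_binary_indicator(y_true, pos_label))) == 2:
        report.auc_roc = auc_roc(scores, y_true, pos_label)
        report.auc_pr = auc_pr(scores, y_true, pos_label)
    return report


def cross_validate(
    X,
    y,
    fit_fn,
    plan: CVPlan | None = None,
    pos_label=None,
) -> CVResult:
    """Cross-validate a classifier factory over a feature matrix.

    ``fit_fn(X_train, y_train)`` must return a fitted object exposing
    ``predict`` (and ``predict_proba`` plus ``classes_`` for AUCs).
    For binary problems pass ``pos_label`` to obtain the full metric set;
    otherwise only accuracy is reported. Each instance is tested exactly
    once; with ``scheme='loocv'`` the report is computed from the pooled
    leave-one-out predictions (per-fold metrics are degenerate at fold
    size one), and ``fold_reports`` is empty.
    """
    plan = plan or CVPlan()
    X_arr = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X)
    if np.isnan(X_arr.astype(float)).any():
        raise ValueError("feature matrix contains NaN")
    y = np.asarray(y)
    n = X_arr.shape[0]
    fold_reports: list[MetricsReport] = []
    assignments: list[np.ndarray] = []
    pooled_pred = np.empty(n, dtype=y.dtype)
    pooled_scores = np.full(n, np.nan)
    seen = np.zeros(n, dtype=bool)
    for train_idx, test_idx in plan.splitter().split(X_arr, y):
        if np.intersect1d(train_idx, test_idx).size:
            raise AssertionError("train/test folds overlap")
        if np.unique(y[train_idx]).shape[0] < 2:
            raise ValueError("a class is absent from a training fold")
        model = fit_fn(_take(X, train_idx), y[train_idx])
        y_pred, scores = _evaluate_split(model, _take(X, test_idx), y[test_idx], pos_label)
        if seen[test_idx].any():
            raise AssertionError("an instance appears in two test folds")
        seen[test_idx] = True
        pooled_pred[test_idx] = y_pred
        if scores is not None:
            pooled_scores[test_idx] = scores
        assignments.append(np.asarray(test_idx))
        if plan.scheme != "loocv":
            if pos_label is not None:
                fold_reports.append(
                    _binary_report(y[test_idx], y_pred, scores, pos_label)
                )
            else:
                fold_reports.append(
                    MetricsReport(accuracy=float(np.mean(y_pred == y[test_idx])))
                )
    if not seen.all():
        raise AssertionError("some instances were never tested")
    scores_ok = not np.isnan(pooled_scores).any()
    if plan.scheme == "loocv":
        if pos_label is not None:
            mean = _binary_report(
                y, pooled_pred, pooled_scores if scores_ok else None, pos_label
            )
        else:
            mean = MetricsReport(accuracy=float(np.mean(pooled_pred == y)))
        return CVResult(fold_reports=[], mean=mean, assignments=assignments)
    mean = MetricsReport(
        **{
            f: float(np.nanmean([getattr(r, f) for r in fold_reports]))
            if not all(math.isnan(getattr(r, f)) for r in fold_reports)
            else math.nan
            for f in METRIC_FIELDS
        }
    )
    return CVResult(fold_reports=fold_reports, mean=mean, assignments=assignments)


def _take(X, idx):
    if isinstance(X, pd.DataFrame):
        return X.iloc[idx]
    return np.asarray(X)[idx]


# ---------------------------------------------------------------------------
# Balanced resampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResamplingPlan:
    """Repeated equal-size positive/negative draws (default 100 samples)."""

    n_samples: int = 100
    draw_size: int | None = None  # per class; default min(pool sizes)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def balanced_resample_eval(
    pos_X: pd.DataFrame,
    neg_X: pd.DataFrame,
    fit_fn,
    plan: ResamplingPlan | None = None,
    cv_plan: CVPlan | None = None,
) -> MetricsReport:
    """Evaluate over repeated balanced draws from a positive and a negative
    pool of encoded sequences.

    Each sample draws ``draw_size`` rows without replacement from each
    pool, runs ``cross_validate``, and the report is the mean of the
    per-sample mean metrics with standard errors over samples (zero when
    ``n_samples == 1``). Fully reproducible from ``plan.seed``.
    """
    plan = plan or ResamplingPlan()
    cv_plan = cv_plan or CVPlan()
    n_pos, n_neg = len(pos_X), len(neg_X)
    size = plan.draw_size if plan.draw_size is not None else min(n_pos, n_neg)
    if size > n_pos or size > n_neg:
        raise ValueError(
            f"draw size {size} exceeds pool sizes ({n_pos} positive, {n_neg} negative)"
        )
    rng = np.random.default_rng(plan.seed)
    per_sample: list[MetricsReport] = []
    for _ in range(plan.n_samples):
        pi = rng.choice(n_pos, size=size, replace=False)
        ni = rng.choice(n_neg, size=size, replace=False)
        X = pd.concat([pos_X.iloc[pi], neg_X.iloc[ni]], axis=0)
        y = np.array(["pos"] * size + ["neg"] * size)
        fold_plan = CVPlan(
            scheme=cv_plan.scheme,
            k=cv_plan.k,
            stratified=cv_plan.stratified,
            seed=int(rng.integers(2**31)),
        )
        per_sample.append(cross_validate(X, y, fit_fn, fold_plan, pos_label="pos").mean)
    means, ses = {}, {}
    for f in METRIC_FIELDS:
        vals = np.array([getattr(r, f) for r in per_sample])
        means[f] = float(np.nanmean(vals)) if not np.isnan(vals).all() else math.nan
        if plan.n_samples == 1 or np.isnan(vals).all():
            ses[f] = 0.0
        else:
            ses[f] = float(np.nanstd(vals, ddof=1) / math.sqrt(plan.n_samples))
    return MetricsReport(**means, se=ses)


# ---------------------------------------------------------------------------
# One-vs-rest family evaluation
# ---------------------------------------------------------------------------

def one_vs_rest_family_eval(
    X: pd.DataFrame,
    families,
    fit_fn,
    plan: CVPlan | None = None,
) -> tuple[dict[str, MetricsReport], MetricsReport]:
    """Binary evaluation per family (that family positive, the union of the
    others negative) plus class-size-weighted average metrics."""
    plan = plan or CVPlan()
    families = np.asarray(families)
    classes, counts = np.unique(families, return_counts=True)
    if classes.shape[0] < 2:
        raise ValueError("need at least two families")
    per_family: dict[str, MetricsReport] = {}
    for fam in classes:
        y_bin = np.where(families == fam, fam, "rest")
        per_family[str(fam)] = cross_validate(X, y_bin, fit_fn, plan, pos_label=fam).mean
    weights = counts / counts.sum()
    avg = {}
    for f in METRIC_FIELDS:
        vals = np.array([getattr(per_family[str(c)], f) for c in classes])
        ok = ~np.isnan(vals)
        avg[f] = float(np.sum(weights[ok] * vals[ok]) / weights[ok].sum()) if ok.any() else math.nan
    return per_family, MetricsReport(**avg)
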