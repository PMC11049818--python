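"""Dataset balancing, splitting, cross-validation, metrics, and baselines.

The evaluation protocol: the larger class is randomly downsampled to the
smaller (seeded, without replacement); records are split per class
80:20 into training and test, then the training part 80:20 again into
training and validation, with floor rounding at both stages; model
selection uses stratified 5-fold cross-validation on the training set;
performance is reported as accuracy, precision, sensitivity,
specificity, F1 and the Matthews correlation coefficient, plus ROC/AUC:

    ACC = (TP + TN) / (TP + FP + TN + FN)
    P   = TP / (TP + FP)
    SN  = TP / (TP + FN)
    SP  = TN / (TN + FP)
    F1  = 2 TP / (2 TP + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

AUC is computed as the Mann-Whitney pair statistic
P(score_pos > score_neg) + 0.5 * P(tie), which equals the area under the
tie-handled ROC curve.

Four classical baseline families (RBF-kernel SVM, random forest,
Gaussian naive Bayes, gradient-boosted trees) run with the tuned
hyperparameter sets as defaults.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .sequence_io import ProteinRecord, ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    ACC: float
    P: float
    SN: float
    SP: float
    F1: float
    MCC: float
    AUC: Optional[float] = None
    per_fold: list["MetricsReport"] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("ACC", "P", "SN", "SP", "F1", "MCC")}
        if self.AUC is not None:
            d["AUC"] = self.AUC
        return d


@dataclass(frozen=True)
class SplitCounts:
    train: dict[int, int]
    val: dict[int, int]
    test: dict[int, int]


@dataclass(frozen=True)
class ThreeWaySplit:
    counts: SplitCounts
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


@dataclass(frozen=True)
class AttributionMatrix:
    """Per-sample, per-feature attribution values with feature-group tags."""

    values: np.ndarray  # samples x features
    group_tags: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[1] != len(self.group_tags):
            raise ValidationError("group_tags must cover every feature column")


def balance_by_downsampling(
    pos: Sequence[ProteinRecord], neg: Sequence[ProteinRecord], seed: int = 42
) -> list[ProteinRecord]:
    """Downsample the larger class to the smaller one, seeded and reproducible.

    Sampling is without replacement via ``random.Random(seed).sample``;
    output order is positives then negatives, each in sampled order.
    """
    if not pos or not neg:
        raise ValidationError("both classes must be non-empty")
    pos, neg = list(pos), list(neg)
    rng = random.Random(seed)
    if len(pos) > len(neg):
        pos = rng.sample(pos, len(neg))
    elif len(neg) > len(pos):
        neg = rng.sample(neg, len(pos))
    return pos + neg


def _floor_split(n: int, test_frac: float, val_frac: float) -> tuple[int, int, int]:
    test = math.floor(test_frac * n)
    val = math.floor(val_frac * (n - test))
    train = n - test - val
    return train, val, test


def stratified_three_way_split(
    records: Sequence[ProteinRecord],
    test_frac: float = 0.2,
    val_frac: float = 0.2,
    seed: int = 0,
) -> ThreeWaySplit:
    """Per-class train/validation/test split with floor rounding at both stages.

    Per class: ``test = floor(test_frac * N)``, then
    ``val = floor(val_frac * (N - test))``, remainder trains.  Index sets
    are disjoint and exhaustive; the shuffle inside each class is seeded.
    """
    labels = np.array([r.label for r in records])
    if any(l is None for l in labels):
        raise ValidationError("all records need labels for splitting")
    rng = np.random.default_rng(seed)
    train_parts, val_parts, test_parts = [], [], []
    counts_train, counts_val, counts_test = {}, {}, {}
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 3:
            raise ValidationError(f"class {cls} has fewer than 3 samples")
        n_train, n_val, n_test = _floor_split(len(idx), test_frac, val_frac)
        perm = rng.permutation(idx)
        test_parts.append(perm[:n_test])
        val_parts.append(perm[n_test : n_test + n_val])
        train_parts.append(perm[n_test + n_val :])
        counts_train[cls], counts_val[cls], counts_test[cls] = n_train, n_val, n_test
    return ThreeWaySplit(
        counts=SplitCounts(train=counts_train, val=counts_val, test=counts_test),
        train_idx=np.sort(np.concatenate(train_parts)),
        val_idx=np.sort(np.concatenate(val_parts)),
        test_idx=np.sort(np.concatenate(test_parts)),
    )


def kfold_plan(
    train_indices: Sequence[int], labels: Sequence[int], k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partition of the training indices.

    Returns (fit, holdout) index pairs; holdouts are disjoint, exhaustive
    and near-equal in size (differ by at most one).
    """
    from sklearn.model_selection import StratifiedKFold

    idx = np.asarray(train_indices)
    y = np.asarray(labels)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if len(idx) < k:
        raise ValidationError(f"need at least k = {k} samples, got {len(idx)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(idx[fit], idx[hold]) for fit, hold in skf.split(np.zeros(len(idx)), y)]


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """The six confusion-matrix metrics; MCC = 0 when a denominator factor is 0."""
    if c.total == 0:
        raise ValidationError("empty confusion matrix")
    tp, fp, tn, fn = float(c.TP), float(c.FP), float(c.TN), float(c.FN)
    acc = (tp + tn) / (tp + fp + tn + fn)
    p = tp / (tp + fp) if tp + fp else 0.0
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return MetricsReport(ACC=acc, P=p, SN=sn, SP=sp, F1=f1, MCC=mcc)


def confusion_from_predictions(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    yt, yp = np.asarray(y_true, int), np.asarray(y_pred, int)
    return ConfusionCounts(
        TP=int(((yt == 1) & (yp == 1)).sum()),
        FP=int(((yt == 0) & (yp == 1)).sum()),
        TN=int(((yt == 0) & (yp == 0)).sum()),
        FN=int(((yt == 1) & (yp == 0)).sum()),
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, float]:
    """ROC points and AUC via the Mann-Whitney pair statistic.

    AUC = P(score_pos > score_neg) + 0.5 * P(score_pos = score_neg),
    computed exactly over all positive-negative pairs via ranking; the
    returned ROC points are (FPR, TPR) at every distinct threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("roc_auc requires both classes present")
    from scipy.stats import rankdata

    ranks = rankdata(s)  # average ranks handle ties
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-s, kind="mergesort")
    ys = y[order]
    ss = s[order]
    tps = np.cumsum(ys == 1)
    fps = np.cumsum(ys == 0)
    distinct = np.flatnonzero(np.diff(ss, append=np.nan) != 0)
    points = np.column_stack([
        np.concatenate([[0.0], fps[distinct] / n_neg]),
        np.concatenate([[0.0], tps[distinct] / n_pos]),
    ])
    return points, float(auc)


def aggregate_group_importance(a: AttributionMatrix) -> list[tuple[str, float]]:
    """Mean |attribution| per feature, averaged within groups, sorted descending."""
    groups = sorted(set(a.group_tags))
    per_feature = np.abs(a.values).mean(axis=0)
    scores = {}
    tags = np.asarray(a.group_tags)
    for g in groups:
        cols = np.flatnonzero(tags == g)
        if cols.size == 0:
            raise ValidationError(f"group {g!r} has no features")
        scores[g] = float(per_feature[cols].mean())
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))


# -- baseline families -------------------------------------------------------

#: Tuned hyperparameters used as the center of any grid search.
BASELINE_DEFAULTS: dict[str, dict] = {
    "svm": {"C": 10, "gamma": "scale", "decision_function_shape": "ovr",
            "kernel": "rbf"},
    "rf": {"n_estimators": 1000, "max_depth": 3, "random_state": 0, "n_jobs": -1},
    "nb": {"priors": None, "var_smoothing": 1e-9},
    "xgb": {"max_depth": 15, "learning_rate": 0.1, "n_estimators": 2000,
            "min_child_weight": 5, "max_delta_step": 0, "subsample": 0.8,
            "colsample_bytree": 0.7, "reg_alpha": 0, "reg_lambda": 0.4,
            "scale_pos_weight": 0.8, "objective": "binary:logistic",
            "eval_metric": "auc", "seed": 1440, "gamma": 0},
}


def make_baseline(name: str, overrides: Optional[dict] = None, seed: Optional[int] = None):
    """Instantiate a baseline estimator with the tuned defaults."""
    if name not in BASELINE_DEFAULTS:
        raise ValidationError(f"unknown baseline {name!r}; choose from {sorted(BASELINE_DEFAULTS)}")
    params = dict(BASELINE_DEFAULTS[name])
    if overrides:
        params.update(overrides)
    if name == "svm":
        from sklearn.svm import SVC

        if seed is not None:
            params.setdefault("random_state", seed)
        return SVC(**params)
    if name == "rf":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(**params)
    if name == "nb":
        from sklearn.naive_bayes import GaussianNB

        return GaussianNB(**params)
    from xgboost import XGBClassifier

    return XGBClassifier(**params)


def _score_of(estimator, X: np.ndarray) -> np.ndarray:
    if hasattr(estimator, "predict_proba"):
        return estimator.predict_proba(X)[:, 1]
    return estimator.decision_function(X)


def evaluate_split(estimator, X_train, y_train, X_test, y_test) -> MetricsReport:
    """Fit on the training part and report all metrics on the held-out part."""
    import warnings as _w

    X_train = np.asarray(X_train, float)
    if np.allclose(X_train.var(axis=0), 0.0):
        _w.warn("feature matrix has zero variance everywhere", stacklevel=2)
    estimator.fit(X_train, np.asarray(y_train, int))
    y_pred = estimator.predict(np.asarray(X_test, float))
    report = compute_metrics(confusion_from_predictions(y_test, y_pred))
    _, report.AUC = roc_auc(_score_of(estimator, np.asarray(X_test, float)), y_test)
    return report


def cross_validate(
    make_estimator, X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0
) -> MetricsReport:
    """Stratified k-fold CV; the summary report holds fold means, per_fold the folds."""
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    folds = kfold_plan(np.arange(len(y)), y, k=k, seed=seed)
    reports = [
        evaluate_split(make_estimator(), X[fit], y[fit], X[hold], y[hold])
        for fit, hold in folds
    ]
    mean = {m: float(np.mean([getattr(r, m) for r in reports]))
            for m in ("ACC", "P", "SN", "SP", "F1", "MCC", "AUC")}
    summary = MetricsReport(**{k_: v for k_, v in mean.items() if k_ != "AUC"},
                            AUC=mean["AUC"])
    summary.per_fold = reports
    return summary


def fold_mean_sd(summary: MetricsReport, metric: str) -> tuple[float, float]:
    """Mean +/- sample standard deviation of a metric across folds."""
    vals = np.array([getattr(r, metric) for r in summary.per_fold], dtype=float)
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return float(vals.mean()), sd


def run_baselines(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    seed: int = 0,
    models: Sequence[str] = ("svm", "rf", "nb", "xgb"),
    overrides: Optional[dict[str, dict]] = None,
) -> dict[str, MetricsReport]:
    """Cross-validate the four classical baseline families."""
    out = {}
    overrides = overrides or {}
    for name in models:
        out[name] = cross_validate(
            lambda name=name: make_baseline(name, overrides.get(name), seed=seed),
            features, labels, k=k, seed=seed,
        )
    return out
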