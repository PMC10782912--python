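"""Classifier evaluation: confusion matrix, threshold metrics, ROC/AUC,
prediction-label correlation, bootstrap AUC, and cross-validation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "RocCurve",
    "EvalReport",
    "BootstrapResult",
    "confusion",
    "metrics",
    "roc_auc",
    "pearson_corr",
    "bootstrap_auc",
    "evaluate_predictions",
    "cross_validate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass
class EvalReport:
    confusion: ConfusionMatrix
    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None
    roc: RocCurve
    auc: float
    pearson_r: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "confusion": {"tp": self.confusion.tp, "fp": self.confusion.fp,
                          "tn": self.confusion.tn, "fn": self.confusion.fn},
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
        }


@dataclass
class BootstrapResult:
    n_reps: int
    auc_samples: np.ndarray
    mean_auc: float
    ci95: tuple[float, float]
    seed: int
    n_redrawn: int


def confusion(y, p, threshold: float = 0.5) -> ConfusionMatrix:
    """2x2 confusion matrix; a sample is called positive iff ``p > threshold``
    (strictly)."""
    y = np.asarray(y)
    p = np.asarray(p, dtype=float)
    if len(y) != len(p):
        raise ValueError("y and p must have equal length")
    if len(y) == 0:
        raise ValueError("empty input")
    pred = p > threshold
    actual = y == 1
    return ConfusionMatrix(
        tp=int((pred & actual).sum()),
        fp=int((pred & ~actual).sum()),
        tn=int((~pred & ~actual).sum()),
        fn=int((~pred & actual).sum()),
    )


def metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Accuracy, precision, recall, F1.  Metrics with a zero denominator are
    reported as None (undefined), never coerced to 0."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total
    precision = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) > 0 else None
    recall = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else None
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}


def roc_auc(y, p) -> RocCurve:
    """ROC by sweeping the unique scores as thresholds; AUC by trapezoid.

    Ties in scores receive half credit, so the AUC equals the normalized
    Mann-Whitney pair statistic.
    """
    y = np.asarray(y)
    p = np.asarray(p, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-p, kind="stable")
    ys = y[order]
    ps = p[order]
    # cumulative counts after each tie block
    distinct = np.r_[np.flatnonzero(np.diff(ps)), len(ps) - 1]
    tp_cum = np.cumsum(ys == 1)[distinct]
    fp_cum = np.cumsum(ys == 0)[distinct]
    tpr = np.r_[0.0, tp_cum / n_pos]
    fpr = np.r_[0.0, fp_cum / n_neg]
    thresholds = np.r_[np.inf, ps[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def _auc_rank(y: np.ndarray, p: np.ndarray) -> float:
    """AUC via midranks (equal to the trapezoid sweep); used in the bootstrap
    loop for speed."""
    n_pos = int((y == 1).sum())
    n_neg = len(y) - n_pos
    ranks = stats.rankdata(p)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def pearson_corr(y, p) -> tuple[float, float]:
    """Product-moment correlation between labels and predictions with the
    two-sided t-distribution p-value (n-2 df)."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(y) == 0 or np.std(p) == 0:
        raise ValueError("zero variance in labels or predictions")
    r, pv = stats.pearsonr(y, p)
    return float(r), float(pv)


def bootstrap_auc(y, p, n_reps: int = 10_000, seed: int = 0) -> BootstrapResult:
    """Percentile-bootstrap distribution of the AUC.

    Each replicate resamples (label, prediction) pairs with replacement to
    the original size; replicates that draw a single class are redrawn (the
    count is reported).
    """
    y = np.asarray(y)
    p = np.asarray(p, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("bootstrap requires both classes present")
    rng = np.random.default_rng(seed)
    n = len(y)
    samples = np.empty(n_reps)
    n_redrawn = 0
    for i in range(n_reps):
        while True:
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if yb.min() != yb.max():
                break
            n_redrawn += 1
        samples[i] = _auc_rank(yb, p[idx])
    lo, hi = np.percentile(samples, [2.5, 97.5])
    return BootstrapResult(
        n_reps=n_reps,
        auc_samples=samples,
        mean_auc=float(samples.mean()),
        ci95=(float(lo), float(hi)),
        seed=seed,
        n_redrawn=n_redrawn,
    )


def evaluate_predictions(y, p, threshold: float = 0.5) -> EvalReport:
    """Full report: confusion, threshold metrics, ROC/AUC, correlation."""
    cm = confusion(y, p, threshold)
    m = metrics(cm)
    roc = roc_auc(y, p)
    try:
        r, pv = pearson_corr(y, p)
    except ValueError:  # degenerate (constant) predictions
        r, pv = float("nan"), float("nan")
    return EvalReport(
        confusion=cm,
        accuracy=m["accuracy"],
        precision=m["precision"],
        recall=m["recall"],
        f1=m["f1"],
        roc=roc,
        auc=roc.auc,
        pearson_r=r,
        p_value=pv,
    )


def cross_validate(X, y, k: int = 10, cfg=None, seed: int = 0):
    """Seeded stratified k-fold cross-validation of the classifier.

    Each fold trains a fresh model on the remaining folds and evaluates on
    the held-out fold.  Returns (list of EvalReport, accuracy SD).
    """
    from sklearn.model_selection import StratifiedKFold

    from .model import ModelConfig, predict, train

    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"each class needs >= {k} samples for {k}-fold CV, got {counts.tolist()}"
        )
    cfg = cfg or ModelConfig()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        fold_cfg = replace(cfg, seed=cfg.seed + fold)
        tm = train(X[train_idx], y[train_idx], cfg=fold_cfg)
        p = predict(tm, X[test_idx])
        reports.append(evaluate_predictions(y[test_idx], p, cfg.threshold))
    acc_sd = float(np.std([r.accuracy for r in reports], ddof=1))
    return reports, acc_sd
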