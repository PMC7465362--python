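"""10-fold cross-validation protocol and threshold/rank performance metrics.

The CV protocol shuffles the dataset (stratified), cuts it into k near-equal
folds, and in rotation j uses fold j as the test fold, fold (j+1) mod k as the
validation fold (for early stopping / checkpointing), and the remaining k-2
folds for training — the 8/1/1 role split at k = 10. Per-rotation metrics are
aggregated by their mean.

Metrics are the standard confusion-matrix quartet

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    ACC = (TP+TN) / (TP+TN+FP+FN)
    Sn  = TP / (TP+FN)
    Sp  = TN / (TN+FP)

(MCC defined as 0 when its denominator vanishes) plus the ROC curve swept
over the unique scores and its trapezoidal AUC, which equals the normalized
Mann–Whitney U statistic with ties counted half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .encoders import encode_dataset
from .model import ArchitectureSpec, TrainConfig, train
from .seqio import LabeledDataset


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true, y_prob, threshold: float = 0.5) -> ConfusionCounts:
    """Count TP/TN/FP/FN by calling positive where ``y_prob >= threshold``."""
    y_true = np.asarray(y_true).ravel()
    y_prob = np.asarray(y_prob, dtype=float).ravel()
    if y_true.shape != y_prob.shape:
        raise ValueError(
            f"length mismatch: y_true has {y_true.size}, y_prob has {y_prob.size}")
    pred = y_prob >= threshold
    pos = y_true == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def metrics(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(MCC, ACC, Sn, Sp) from confusion counts; 0/0 ratios defined as 0."""
    if c.total == 0:
        raise ValueError("cannot compute metrics of empty confusion counts")
    tp, tn, fp, fn = float(c.tp), float(c.tn), float(c.fp), float(c.fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    acc = (tp + tn) / c.total
    sn = 0.0 if tp + fn == 0 else tp / (tp + fn)
    sp = 0.0 if tn + fp == 0 else tn / (tn + fp)
    return mcc, acc, sn, sp


def roc_auc(y_true, y_prob) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) from a sweep over unique scores, and the
    trapezoidal AUC (= P[score_pos > score_neg] + ties/2)."""
    y_true = np.asarray(y_true).ravel()
    y_prob = np.asarray(y_prob, dtype=float).ravel()
    if y_true.shape != y_prob.shape:
        raise ValueError("y_true and y_prob must have equal length")
    n_pos = int(np.sum(y_true == 1))
    n_neg = y_true.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-y_prob, kind="stable")
    sorted_true = y_true[order]
    sorted_score = y_prob[order]
    tps = np.cumsum(sorted_true == 1)
    fps = np.cumsum(sorted_true == 0)
    # keep the last index of each tied score block (threshold sweep)
    last = np.r_[np.nonzero(np.diff(sorted_score))[0], y_true.size - 1]
    tpr = np.r_[0.0, tps[last] / n_pos]
    fpr = np.r_[0.0, fps[last] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


@dataclass
class FoldPlan:
    """Index sets for the k train/validation/test rotations."""

    k: int
    seed: int
    folds: list[np.ndarray]  # partition of range(n) into k near-equal folds

    @property
    def n(self) -> int:
        return sum(len(f) for f in self.folds)

    def rotation(self, j: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(train_idx, val_idx, test_idx) for rotation j: test fold j,
        validation fold (j+1) mod k, the rest training."""
        test = self.folds[j]
        val = self.folds[(j + 1) % self.k]
        train_idx = np.concatenate(
            [self.folds[i] for i in range(self.k) if i not in (j, (j + 1) % self.k)])
        return train_idx, val, test

    def rotations(self):
        return (self.rotation(j) for j in range(self.k))


def make_folds(ds_or_labels, k: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified shuffle into k near-equal folds; deterministic per seed.

    Accepts a :class:`LabeledDataset` or a label vector. Requires k >= 3
    (train/validation/test roles) and at least k records per class.
    """
    if k < 3:
        raise ValueError(f"k must be >= 3 to assign train/val/test roles, got {k}")
    labels = np.asarray(
        ds_or_labels.labels() if isinstance(ds_or_labels, LabeledDataset)
        else ds_or_labels)
    for cls in np.unique(labels):
        if np.sum(labels == cls) < k:
            raise ValueError(
                f"class {cls} has {np.sum(labels == cls)} records, need >= {k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [test for _, test in skf.split(np.zeros(len(labels)), labels)]
    return FoldPlan(k=k, seed=seed, folds=folds)


@dataclass
class FoldMetrics:
    fold: int
    mcc: float
    acc: float
    sn: float
    sp: float
    auc: float
    counts: ConfusionCounts | None = None


@dataclass
class MetricsReport:
    """Mean-over-folds metrics with the per-fold breakdown retained."""

    mcc: float
    acc: float
    sn: float
    sp: float
    auc: float
    per_fold: list[FoldMetrics] = field(default_factory=list)
    aggregation: str = "mean"

    @classmethod
    def from_folds(cls, per_fold: list[FoldMetrics]) -> "MetricsReport":
        arr = {m: float(np.mean([getattr(f, m) for f in per_fold]))
               for m in ("mcc", "acc", "sn", "sp", "auc")}
        return cls(per_fold=per_fold, **arr)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {k: v for k, v in asdict(f).items() if k != "counts"}
            for f in self.per_fold
        ]
        rows.append(dict(fold="mean", mcc=self.mcc, acc=self.acc,
                         sn=self.sn, sp=self.sp, auc=self.auc))
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        import json

        return json.dumps(
            dict(mean=dict(mcc=self.mcc, acc=self.acc, sn=self.sn,
                           sp=self.sp, auc=self.auc),
                 per_fold=[{k: v for k, v in asdict(f).items() if k != "counts"}
                           for f in self.per_fold]),
            indent=2)


def evaluate_predictions(y_true, y_prob, threshold: float = 0.5,
                         fold: int = 0) -> FoldMetrics:
    c = confusion(y_true, y_prob, threshold)
    mcc, acc, sn, sp = metrics(c)
    _, auc = roc_auc(y_true, y_prob)
    return FoldMetrics(fold=fold, mcc=mcc, acc=acc, sn=sn, sp=sp,
                       auc=auc, counts=c)


def cross_validate(ds: LabeledDataset, scheme: str,
                   arch: ArchitectureSpec | None = None,
                   cfg: TrainConfig | None = None,
                   k: int = 10, seed: int = 0,
                   return_models: bool = False):
    """Train and test the classifier over the k-rotation fold plan.

    Each rotation trains a fresh model on its k-2 training folds (early
    stopping against its validation fold) and scores its test fold; the
    report carries per-fold metrics and their mean. Test records are never
    part of their own rotation's training or validation folds.
    """
    arch = arch or ArchitectureSpec()
    cfg = cfg or TrainConfig()
    X, y = encode_dataset(ds, scheme)
    plan = make_folds(ds, k=k, seed=seed)
    per_fold = []
    models = []
    for j, (tr, val, test) in enumerate(plan.rotations()):
        fold_cfg = TrainConfig(**{**asdict(cfg), "seed": cfg.seed + j})
        est = train(X[tr], y[tr], X[val], y[val], arch=arch, cfg=fold_cfg)
        y_prob = est.predict_proba(X[test])[:, 1]
        per_fold.append(evaluate_predictions(y[test], y_prob, fold=j))
        if return_models:
            models.append(est)
    report = MetricsReport.from_folds(per_fold)
    return (report, plan, models) if return_models else report
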