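"""Classifier evaluation: confusion counts, SEN/SPE/ACC/F1, ROC/AUC,
and subject-level k-fold cross-validation.

The positive class is MCI (label 1).  The metrics are

    SEN = TP / (TP + FN)            (sensitivity, recall on MCI)
    SPE = TN / (TN + FP)            (specificity)
    ACC = (TP + TN) / total
    F1  = 2 * PRE * SEN / (PRE + SEN),  PRE = TP / (TP + FP)

Ratios with a zero denominator are reported as NaN with a warning
rather than silently coerced to 0, so fold averages stay honest.
Evaluation is per scan while splitting stays per subject.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics

from . import autodiff as ad
from .architecture import ModelConfig, build_model
from .data_io import Cohort

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "ROCCurve",
    "confusion",
    "metrics",
    "roc_auc",
    "predict",
    "evaluate_model",
    "cross_validate",
]


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class MetricReport:
    SEN: float
    SPE: float
    ACC: float
    F1: float
    AUC: float
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("SEN", "SPE", "ACC", "F1", "AUC")}
        d["counts"] = self.counts.to_dict()
        return d


@dataclasses.dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self):
        if not (np.all(np.diff(self.fpr) >= 0) and np.all(np.diff(self.tpr) >= 0)):
            raise ValueError("ROC coordinates must be non-decreasing")

    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


def confusion(labels, predictions) -> ConfusionCounts:
    """Four-way tally with MCI (1) as the positive class."""
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.shape != predictions.shape:
        raise ValueError(
            f"labels and predictions differ in length: {labels.shape} vs {predictions.shape}"
        )
    if labels.size == 0:
        raise ValueError("empty evaluation set")
    return ConfusionCounts(
        TP=int(((labels == 1) & (predictions == 1)).sum()),
        TN=int(((labels == 0) & (predictions == 0)).sum()),
        FP=int(((labels == 0) & (predictions == 1)).sum()),
        FN=int(((labels == 1) & (predictions == 0)).sum()),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return num / den


def metrics(counts: ConfusionCounts, auc: float = float("nan")) -> MetricReport:
    """Sensitivity, specificity, accuracy and F1 from confusion counts."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero scans")
    sen = _ratio(counts.TP, counts.TP + counts.FN, "SEN")
    spe = _ratio(counts.TN, counts.TN + counts.FP, "SPE")
    acc = (counts.TP + counts.TN) / counts.total
    pre = _ratio(counts.TP, counts.TP + counts.FP, "PRE")
    if np.isnan(pre) or np.isnan(sen) or (pre + sen) == 0:
        warnings.warn("F1 undefined; reporting NaN", stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2 * pre * sen / (pre + sen)
    return MetricReport(SEN=sen, SPE=spe, ACC=acc, F1=f1, AUC=auc, counts=counts)


def roc_auc(scores, labels) -> tuple[ROCCurve, float]:
    """ROC curve over all score thresholds and its trapezoidal area.

    Ties in the scores are handled by the rank formulation (equivalent
    to counting tied positive/negative pairs as half-concordant).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    present = np.unique(labels)
    if not (0 in present and 1 in present):
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = skmetrics.roc_curve(labels, scores, drop_intermediate=False)
    auc = float(skmetrics.roc_auc_score(labels, scores))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr), auc


# --------------------------------------------------------------------------
# model evaluation
# --------------------------------------------------------------------------

def predict(model, X: np.ndarray, batch_size: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Class predictions (argmax) and MCI softmax scores for (N,1,D,H,W)."""
    model.eval()
    preds, scores = [], []
    for lo in range(0, len(X), batch_size):
        logits = model(ad.Tensor(X[lo : lo + batch_size])).data
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        preds.append(logits.argmax(axis=1))
        scores.append(p[:, 1])
    return np.concatenate(preds), np.concatenate(scores)


def evaluate_model(model, cohort: Cohort, batch_size: int = 8) -> tuple[MetricReport, ROCCurve]:
    """Per-scan evaluation of a trained model on a cohort."""
    vols = cohort.load_volumes()
    X = np.stack([v.voxels for v in vols])[:, None].astype(np.float32)
    y = np.array([v.label for v in vols], dtype=int)
    preds, scores = predict(model, X, batch_size)
    counts = confusion(y, preds)
    if len(np.unique(y)) == 2:
        curve, auc = roc_auc(scores, y)
    else:  # single-class test sets: AUC undefined
        warnings.warn("AUC undefined on a single-class cohort; reporting NaN")
        curve, auc = None, float("nan")
    return metrics(counts, auc=auc), curve


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

def _stratified_subject_folds(cohort: Cohort, k: int, rng: np.random.Generator) -> list[set[str]]:
    labels = cohort.subject_labels()
    folds: list[set[str]] = [set() for _ in range(k)]
    for cls in (0, 1):
        subjects = sorted(labels.index[labels == cls])
        if len(subjects) < k:
            raise ValueError(
                f"class {cls} has {len(subjects)} subjects; cannot form {k} folds"
            )
        order = rng.permutation(len(subjects))
        for pos, i in enumerate(order):
            folds[pos % k].add(subjects[i])
    return folds


def cross_validate(
    cohort: Cohort,
    k: int = 4,
    model_cfg: ModelConfig | None = None,
    train_cfg=None,
    train_fn=None,
) -> tuple[list[MetricReport], pd.DataFrame]:
    """Subject-level stratified k-fold cross-validation.

    Each fold's subjects are held out once; a fresh model is trained on
    the remainder and evaluated per scan on the held-out scans.
    Returns per-fold reports and a mean/sd summary table.  `train_fn`
    may override the default training routine (it receives the train
    cohort and fold index and must return a fitted model).
    """
    from .training import TrainConfig, train as _train  # local import to avoid cycle

    if train_cfg is None:
        train_cfg = TrainConfig()
    if model_cfg is None:
        model_cfg = ModelConfig()
    rng = np.random.default_rng(int(train_cfg.seed) & 0x7FFFFFFF)
    folds = _stratified_subject_folds(cohort, k, rng)

    reports: list[MetricReport] = []
    for fold_idx, held_out in enumerate(folds):
        test = cohort.subset_by_subjects(held_out)
        trainc = cohort.subset_by_subjects(set(cohort.subjects) - held_out)
        assert not set(test.subjects) & set(trainc.subjects)
        if train_fn is not None:
            model = train_fn(trainc, fold_idx)
        else:
            model = build_model(model_cfg, seed=train_cfg.seed + fold_idx)
            _train(model, trainc, train_cfg)
        report, _ = evaluate_model(model, test, batch_size=train_cfg.batch_size)
        reports.append(report)

    frame = pd.DataFrame([
        {m: getattr(r, m) for m in ("SEN", "SPE", "ACC", "F1", "AUC")} for r in reports
    ])
    summary = pd.DataFrame({"mean": frame.mean(), "sd": frame.std(ddof=1)})
    return reports, summary
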