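"""Metrics against exact-arithmetic and pair-counting oracles."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mciagaspp import autodiff as ad
from mciagaspp.evaluation import (
    ConfusionCounts,
    confusion,
    cross_validate,
    metrics,
    roc_auc,
)


# --------------------------------------------------------------------------
# confusion counts
# --------------------------------------------------------------------------

def test_confusion_trivial_cases():
    c = confusion([1, 1, 0, 0], [1, 1, 0, 0])
    assert (c.TP, c.TN, c.FP, c.FN) == (2, 2, 0, 0)
    c = confusion([1, 0], [0, 1])
    assert (c.TP, c.TN, c.FP, c.FN) == (0, 0, 1, 1)


def test_confusion_matches_tally_loop(rng):
    labels = rng.integers(0, 2, size=200)
    preds = rng.integers(0, 2, size=200)
    c = confusion(labels, preds)
    tally = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}
    for y, p in zip(labels, preds):
        if y == 1 and p == 1:
            tally["TP"] += 1
        elif y == 0 and p == 0:
            tally["TN"] += 1
        elif y == 0 and p == 1:
            tally["FP"] += 1
        else:
            tally["FN"] += 1
    assert c.to_dict() == tally
    assert c.total == 200


def test_confusion_validation():
    with pytest.raises(ValueError):
        confusion([1, 0], [1])
    with pytest.raises(ValueError):
        confusion([], [])


# --------------------------------------------------------------------------
# scalar metrics
# --------------------------------------------------------------------------

def test_worked_accuracy_120_of_147():
    """A confusion outcome with 120 of 147 scans correct gives 81.63%."""
    report = metrics(ConfusionCounts(TP=55, TN=65, FP=9, FN=18))
    assert report.ACC * 100 == pytest.approx(81.63, abs=0.01)


def test_perfect_classifier_metrics():
    report = metrics(ConfusionCounts(TP=10, TN=12, FP=0, FN=0))
    assert report.SEN == report.SPE == report.ACC == report.F1 == 1.0


@given(
    tp=st.integers(0, 40), tn=st.integers(0, 40),
    fp=st.integers(0, 40), fn=st.integers(0, 40),
)
@settings(deadline=None, max_examples=80)
def test_metrics_match_rational_arithmetic(tp, tn, fp, fn):
    if tp + tn + fp + fn == 0:
        return
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = metrics(ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn))
    assert report.ACC == pytest.approx(float(Fraction(tp + tn, tp + tn + fp + fn)), abs=1e-12)
    if tp + fn:
        assert report.SEN == pytest.approx(float(Fraction(tp, tp + fn)), abs=1e-12)
    else:
        assert np.isnan(report.SEN)
    if tn + fp:
        assert report.SPE == pytest.approx(float(Fraction(tn, tn + fp)), abs=1e-12)
    else:
        assert np.isnan(report.SPE)
    if tp + fp and tp + fn and (2 * tp + fp + fn):
        pre = Fraction(tp, tp + fp)
        sen = Fraction(tp, tp + fn)
        if pre + sen > 0:
            f1 = 2 * pre * sen / (pre + sen)
            assert report.F1 == pytest.approx(float(f1), abs=1e-12)


def test_undefined_metric_reports_nan_with_warning():
    with pytest.warns(UserWarning, match="SEN undefined"):
        report = metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=0))
    assert np.isnan(report.SEN)


# --------------------------------------------------------------------------
# ROC / AUC
# --------------------------------------------------------------------------

def pair_counting_auc(scores, labels):
    """P(score+ > score-) + 0.5 P(tie) over all positive/negative pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auc_trivial_cases():
    _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
    assert auc == 1.0
    _, auc = roc_auc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1])
    assert auc == 0.5


def test_auc_matches_pair_counting_oracle(rng):
    for trial in range(5):
        n = 30
        scores = np.round(rng.random(n), 1)  # coarse scores force ties
        labels = rng.integers(0, 2, size=n)
        if len(np.unique(labels)) < 2:
            continue
        curve, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-9)
        # trapezoidal area under the emitted curve agrees too
        assert np.trapezoid(curve.tpr, curve.fpr) == pytest.approx(auc, abs=1e-9)


def test_roc_curve_shape_invariants(rng):
    scores = rng.random(25)
    labels = rng.integers(0, 2, size=25)
    labels[:2] = [0, 1]
    curve, _ = roc_auc(scores, labels)
    assert curve.fpr[0] == 0 and curve.tpr[0] == 0
    assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1
    assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)


def test_roc_rejects_single_class():
    with pytest.raises(ValueError, match="both classes"):
        roc_auc([0.1, 0.9], [1, 1])


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

class _MaskOracleModel:
    """Stand-in classifier: thresholds mean in-lesion intensity (synthetic
    phantom ground truth), exercising the fold plumbing without training."""

    def __init__(self, mask, threshold):
        self.mask = mask
        self.threshold = threshold

    def eval(self):
        return self

    def __call__(self, x):
        vals = x.data[:, 0][:, self.mask].mean(axis=1)
        logits = np.stack([vals - self.threshold, self.threshold - vals], axis=1)
        return ad.Tensor(logits * 100.0)


def test_cross_validation_partitions_subjects(tiny_cohort, tiny_spec):
    from mciagaspp.phantom import lesion_mask
    from mciagaspp.training import TrainConfig

    mask = lesion_mask(tiny_spec)
    seen: list[set] = []

    def train_fn(train_cohort, fold_idx):
        vols = train_cohort.load_volumes()
        m = np.mean([v.voxels[mask].mean() for v in vols])
        seen.append(set(train_cohort.subjects))
        return _MaskOracleModel(mask, m)

    reports, summary = cross_validate(
        tiny_cohort, k=4, train_cfg=TrainConfig(seed=0), train_fn=train_fn
    )
    assert len(reports) == 4
    held_out = [set(tiny_cohort.subjects) - s for s in seen]
    # every subject held out exactly once; folds partition the subject set
    all_held = [s for fold in held_out for s in fold]
    assert sorted(all_held) == sorted(tiny_cohort.subjects)
    # the oracle classifier separates the phantom classes on every fold
    assert summary.loc["ACC", "mean"] == pytest.approx(1.0)


def test_cross_validation_fold_assignment_deterministic(tiny_cohort, tiny_spec):
    from mciagaspp.phantom import lesion_mask
    from mciagaspp.training import TrainConfig

    mask = lesion_mask(tiny_spec)

    def collect():
        folds = []

        def train_fn(train_cohort, fold_idx):
            folds.append(frozenset(train_cohort.subjects))
            return _MaskOracleModel(mask, 0.5)

        cross_validate(tiny_cohort, k=4, train_cfg=TrainConfig(seed=5), train_fn=train_fn)
        return folds

    assert collect() == collect()


def test_cross_validation_k_exceeding_subjects_rejected(tiny_cohort):
    from mciagaspp.training import TrainConfig

    with pytest.raises(ValueError, match="folds"):
        cross_validate(tiny_cohort, k=5, train_cfg=TrainConfig(seed=0),
                       train_fn=lambda c, i: None)
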