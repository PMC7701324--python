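"""Logistic fitting, prediction, confusion metrics, curves and CV."""

import numpy as np
import pytest
from scipy import sparse
from scipy.stats import mannwhitneyu

from psgkmer import (
    TrainedModel,
    confusion_metrics,
    cross_validate,
    curves_and_areas,
    evaluate,
    fit_lr,
    predict,
)
from psgkmer.encoder import FeatureDescriptor, FeatureMatrix

from conftest import SMALL_FOREST


def _matrix(X, labels=None, names=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = names or [f"FT1:A@{j + 1}-{j + 1}" for j in range(X.shape[1])]
    descs = tuple(
        FeatureDescriptor("FT1", None, None, n, j) for j, n in enumerate(names)
    )
    ids = [f"s{i}" for i in range(X.shape[0])]
    return FeatureMatrix(sparse.csr_matrix(X), descs, ids, labels)


def test_fit_separable_toy_reaches_full_training_accuracy():
    y = np.array([0, 1] * 5)
    m = _matrix(y.reshape(-1, 1), labels=y)
    model = fit_lr(m)
    probs, calls = predict(model, m)
    assert np.array_equal(calls, y)


def test_fit_constant_feature_predicts_prevalence():
    y = np.array([1, 0, 0, 0, 0, 0, 0, 0, 0, 0] * 3)
    m = _matrix(np.ones((30, 1)), labels=y)
    model = fit_lr(m)
    probs, _ = predict(model, m)
    assert np.allclose(probs, y.mean(), atol=0.02)


def test_fit_requires_both_classes():
    with pytest.raises(ValueError):
        fit_lr(_matrix(np.ones((4, 1)), labels=np.ones(4)))


def test_predict_zero_model_gives_half():
    model = TrainedModel(["FT1:A@1-1"], np.zeros(1), 0.0)
    probs, calls = predict(model, _matrix([[3.0], [0.0]]))
    assert np.allclose(probs, 0.5)
    assert list(calls) == [1, 1]  # p >= threshold counts as a positive call


def test_predict_monotone_in_positive_coefficient():
    model = TrainedModel(["FT1:A@1-1"], np.array([2.0]), -1.0)
    probs, _ = predict(model, _matrix([[0.0], [1.0], [2.0]]))
    assert probs[0] < probs[1] < probs[2]


def test_predict_column_mismatch_names_descriptor():
    model = TrainedModel(["FT1:A@1-1", "FT1:A@2-2"], np.zeros(2), 0.0)
    with pytest.raises(ValueError, match="FT1:A@2-2"):
        predict(model, _matrix(np.zeros((1, 2)),
                               names=["FT1:A@1-1", "FT1:A@3-3"]))


def test_model_json_round_trip(tmp_path):
    y = np.array([0, 1] * 6)
    X = np.column_stack([y + 0.1, np.arange(12)])
    m = _matrix(X, labels=y, names=["FT1:A@1-1", "FT11:GC"])
    model = fit_lr(m)
    path = tmp_path / "model.json"
    model.to_json(path)
    back = TrainedModel.from_json(path)
    p1, c1 = predict(model, m)
    p2, c2 = predict(back, m)
    assert np.array_equal(p1, p2) and np.array_equal(c1, c2)
    assert back.metadata["config_digest"] == model.metadata["config_digest"]


def test_confusion_metrics_worked_example():
    """TP=3, FP=1, FN=2, TN=4 -> the six metrics by direct arithmetic."""
    labels = np.array([1] * 5 + [0] * 5)
    calls = np.array([1, 1, 1, 0, 0, 1, 0, 0, 0, 0])
    rep = confusion_metrics(labels, calls)
    assert (rep.tp, rep.fp, rep.fn, rep.tn) == (3, 1, 2, 4)
    assert rep.accuracy == pytest.approx(70.0)
    assert rep.precision == pytest.approx(75.0)
    assert rep.sensitivity == pytest.approx(60.0)
    assert rep.specificity == pytest.approx(80.0)
    assert rep.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35, abs=1e-9)
    assert rep.mcc == pytest.approx(10 / np.sqrt(600), abs=1e-9)
    assert rep.flags == []


def test_confusion_metrics_perfect():
    labels = np.array([1] * 5 + [0] * 5)
    rep = confusion_metrics(labels, labels)
    assert rep.accuracy == 100.0
    assert rep.mcc == 1.0


def test_confusion_metrics_degenerate_flags():
    rep = confusion_metrics(np.ones(4, dtype=int), np.ones(4, dtype=int))
    assert rep.specificity == 0.0
    assert any("specificity" in f for f in rep.flags)
    assert rep.mcc == 0.0


def test_confusion_metrics_length_mismatch():
    with pytest.raises(ValueError):
        confusion_metrics(np.array([1, 0]), np.array([1]))


def test_metric_identity_accuracy_decomposition(rng):
    """accuracy = (sensitivity*P + specificity*N) / (P + N)."""
    for _ in range(20):
        labels = rng.integers(0, 2, size=40)
        if labels.min() == labels.max():
            continue
        calls = rng.integers(0, 2, size=40)
        rep = confusion_metrics(labels, calls)
        p, n = labels.sum(), (1 - labels).sum()
        assert rep.accuracy == pytest.approx(
            (rep.sensitivity * p + rep.specificity * n) / (p + n)
        )


def test_curves_perfect_and_uninformative():
    labels = np.array([0, 0, 1, 1])
    _, auroc, _, aupr = curves_and_areas(labels, labels.astype(float))
    assert auroc == 1.0 and aupr == 1.0
    _, auroc, _, _ = curves_and_areas(labels, np.full(4, 0.3))
    assert auroc == 0.5


def test_curves_random_scores_near_half(rng):
    labels = np.repeat([0, 1], 5000)
    probs = rng.random(10_000)
    _, auroc, _, _ = curves_and_areas(labels, probs)
    assert auroc == pytest.approx(0.5, abs=0.02)


def test_curves_single_class_error():
    with pytest.raises(ValueError):
        curves_and_areas(np.ones(4, dtype=int), np.ones(4))


def test_auroc_equals_rank_statistic(rng):
    """Trapezoid auROC equals the Mann-Whitney U statistic / (P*N)."""
    labels = rng.integers(0, 2, size=200)
    labels[:2] = [0, 1]
    scores = rng.random(200) + 0.3 * labels
    _, auroc, _, _ = curves_and_areas(labels, scores)
    u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
    assert auroc == pytest.approx(
        u / (labels.sum() * (1 - labels).sum()), abs=1e-9
    )


def test_evaluate_report_io(tmp_path, rng):
    labels = np.repeat([0, 1], 20)
    probs = np.clip(0.5 * labels + rng.random(40) * 0.5, 0, 1)
    rep = evaluate(labels, probs)
    rep.to_json(tmp_path / "r.json")
    rep.metrics_table(tmp_path / "r.tsv")
    rep.curves_to_text(tmp_path / "roc.tsv", tmp_path / "pr.tsv")
    assert (tmp_path / "r.json").exists()
    roc_lines = (tmp_path / "roc.tsv").read_text().splitlines()
    assert roc_lines[0] == "fpr\ttpr"
    assert len(roc_lines) == len(rep.roc_points) + 1


def test_cross_validate_planted_signal(planted_dataset):
    report = cross_validate(
        planted_dataset, folds=3, repeats=2, k=5, seed=4, forest=SMALL_FOREST
    )
    assert report.mean["accuracy"] > 75.0
    assert report.mean["auroc"] > 0.8
    assert len(report.per_fold) == 6
    assert len(report.per_repeat) == 2
    # confusion counts pool every held-out prediction
    total = report.tp + report.tn + report.fp + report.fn
    assert total == 2 * len(planted_dataset)


def test_cross_validate_bit_reproducible(planted_dataset):
    a = cross_validate(planted_dataset, folds=3, repeats=1, k=2, seed=9,
                       forest=SMALL_FOREST)
    b = cross_validate(planted_dataset, folds=3, repeats=1, k=2, seed=9,
                       forest=SMALL_FOREST)
    assert a.mean == b.mean and a.std == b.std
    c = cross_validate(planted_dataset, folds=3, repeats=1, k=2, seed=10,
                       forest=SMALL_FOREST)
    assert a.mean != c.mean


def test_cross_validate_leave_one_out_separable():
    """Leave-one-out on a small cleanly separable set is perfect.

    Positives carry one perfect motif per mode group (ACG@1, A-CG@4,
    GG-A@8, A-C-G@12); negatives are built to match none of them.
    """
    from psgkmer import Dataset, SequenceRecord

    records = []
    for i, g in enumerate("ACGUA"):
        seq = f"ACGA{g}CGGG{g}AA{g}C{g}G"
        records.append(SequenceRecord(f"p{i}", seq, 1))
    for i in range(5):
        seq = "U" * i + "C" + "U" * (15 - i)
        records.append(SequenceRecord(f"n{i}", seq, 0))
    ds = Dataset(records)
    report = cross_validate(ds, folds=10, repeats=1, k=2, seed=0,
                            forest=SMALL_FOREST)
    assert report.mean["accuracy"] == 100.0
    assert "auroc" not in report.mean  # single-sample folds have no curves


def test_cross_validate_errors(planted_dataset):
    with pytest.raises(ValueError):
        cross_validate(planted_dataset, folds=1)
    with pytest.raises(ValueError):
        cross_validate(planted_dataset, folds=150, repeats=1)
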