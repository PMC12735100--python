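"""Evaluation metrics against hand-worked examples and scikit-learn oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from macnext.evaluation import (
    ConfusionMatrix,
    aggregate_metrics,
    compute_confusion,
    evaluate_predictions,
    multiclass_auc,
    per_class_metrics,
)


def test_perfect_predictions_are_diagonal():
    labels = ["a", "a", "a", "b", "b", "b", "b", "c", "c", "c"]
    cm = compute_confusion(labels, labels, ["a", "b", "c"])
    assert np.all(cm.counts == np.diag([3, 4, 3]))


def test_direct_tally():
    cm = compute_confusion(["A", "A", "B"], ["A", "B", "B"], ["A", "B"])
    np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])


def test_row_sums_equal_true_counts():
    rng = np.random.default_rng(0)
    truth = rng.integers(0, 5, 200)
    pred = rng.integers(0, 5, 200)
    cm = compute_confusion(truth.tolist(), pred.tolist(), list(range(5)))
    np.testing.assert_array_equal(cm.counts.sum(axis=1), np.bincount(truth, minlength=5))
    assert cm.total == 200


def test_unknown_label_is_named():
    with pytest.raises(ValueError, match="'q'"):
        compute_confusion(["a", "q"], ["a", "a"], ["a", "b"])


def test_hand_worked_two_class_table():
    # counts [[8,2],[1,9]]: class A has TP=8, FP=1, FN=2, TN=9
    cm = ConfusionMatrix(np.array([[8, 2], [1, 9]]), ["A", "B"])
    report = aggregate_metrics(per_class_metrics(cm), cm)
    a = report.per_class["A"]
    assert a["precision"] == pytest.approx(8 / 9, abs=1e-12)
    assert a["recall"] == pytest.approx(0.8, abs=1e-12)
    f1 = 2 * (8 / 9 * 0.8) / (8 / 9 + 0.8)
    assert a["f1"] == pytest.approx(f1, abs=1e-12)
    assert a["accuracy"] == pytest.approx(0.85, abs=1e-12)
    assert report.aggregate["accuracy"] == pytest.approx(17 / 20, abs=1e-12)


def test_binary_one_vs_rest_accuracies_coincide_with_overall():
    cm = ConfusionMatrix(np.array([[13, 4], [6, 27]]), ["A", "B"])
    report = aggregate_metrics(per_class_metrics(cm), cm)
    acc = report.aggregate["accuracy"]
    assert report.per_class["A"]["accuracy"] == pytest.approx(acc, abs=1e-12)
    assert report.per_class["B"]["accuracy"] == pytest.approx(acc, abs=1e-12)


def test_perfect_diagonal_gives_all_ones():
    cm = ConfusionMatrix(np.diag([5, 2, 7]), ["a", "b", "c"])
    report = per_class_metrics(cm)
    for m in report.per_class.values():
        assert all(v == 1.0 for v in m.values())
    assert report.degenerate_classes == []


def test_absent_class_flagged_with_zero_metrics():
    cm = ConfusionMatrix(np.array([[5, 0, 0], [1, 4, 0], [0, 0, 0]]), ["a", "b", "c"])
    report = per_class_metrics(cm)
    assert report.per_class["c"]["precision"] == 0.0
    assert report.per_class["c"]["recall"] == 0.0
    assert "c" in report.degenerate_classes


def test_single_class_degenerate_table():
    cm = ConfusionMatrix(np.array([[11]]), ["only"])
    report = aggregate_metrics(per_class_metrics(cm), cm)
    assert all(v == 1.0 for v in report.aggregate.values())


def test_metrics_invariant_under_relabeling():
    rng = np.random.default_rng(3)
    counts = rng.integers(0, 30, size=(4, 4))
    labels = ["w", "x", "y", "z"]
    cm = ConfusionMatrix(counts, labels)
    rep = aggregate_metrics(per_class_metrics(cm), cm)
    perm = [2, 0, 3, 1]
    cm_p = ConfusionMatrix(counts[np.ix_(perm, perm)], [labels[i] for i in perm])
    rep_p = aggregate_metrics(per_class_metrics(cm_p), cm_p)
    for key, value in rep.aggregate.items():
        assert rep_p.aggregate[key] == pytest.approx(value, abs=1e-12)
    for c in labels:
        assert rep_p.per_class[c] == pytest.approx(rep.per_class[c], abs=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    n=st.integers(2, 8),
    seed=st.integers(0, 10_000),
)
def test_metrics_match_sklearn_oracle(n, seed):
    """Per-class and macro precision/recall/F1 agree with scikit-learn."""
    from sklearn.metrics import precision_recall_fscore_support

    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 25, size=(n, n))
    counts[np.arange(n), np.arange(n)] += 1  # every class appears
    cm = ConfusionMatrix(counts, list(range(n)))
    report = aggregate_metrics(per_class_metrics(cm), cm)

    truth, pred = [], []
    for i in range(n):
        for j in range(n):
            truth += [i] * counts[i, j]
            pred += [j] * counts[i, j]
    p, r, f, _ = precision_recall_fscore_support(
        truth, pred, labels=list(range(n)), zero_division=0
    )
    for i in range(n):
        m = report.per_class[i]
        assert m["precision"] == pytest.approx(p[i], abs=1e-12)
        assert m["recall"] == pytest.approx(r[i], abs=1e-12)
        assert m["f1"] == pytest.approx(f[i], abs=1e-12)
    assert report.aggregate["macro_precision"] == pytest.approx(p.mean(), abs=1e-12)
    assert report.aggregate["macro_recall"] == pytest.approx(r.mean(), abs=1e-12)
    assert report.aggregate["macro_f1"] == pytest.approx(f.mean(), abs=1e-12)
    assert report.aggregate["accuracy"] == pytest.approx(
        np.trace(counts) / counts.sum(), abs=1e-12
    )


# ------------------------------------------------------------------ AUC ----

def test_auc_perfect_separation():
    probs = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])
    assert multiclass_auc([0, 0, 1, 1], probs) == pytest.approx(1.0)


def test_auc_identical_scores_is_chance():
    probs = np.full((10, 2), 0.5)
    truth = [0] * 5 + [1] * 5
    assert multiclass_auc(truth, probs) == pytest.approx(0.5)


def test_auc_matches_pair_counting_oracle():
    # scores for the positive class; count concordant pairs by brute force
    scores = np.array([0.9, 0.8, 0.7, 0.4, 0.3, 0.2])
    truth = np.array([1, 1, 0, 1, 0, 0])
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    pairs = [(1.0 if p > q else 0.5 if p == q else 0.0) for p in pos for q in neg]
    want = np.mean(pairs)
    probs = np.stack([1 - scores, scores], axis=1)
    got, per_class = multiclass_auc(truth, probs, return_per_class=True)
    assert per_class[1] == pytest.approx(want, abs=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(2, 5))
def test_auc_matches_sklearn_oracle(seed, n):
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(seed)
    m = 60
    truth = rng.integers(0, n, m)
    truth[:n] = np.arange(n)  # every class present
    raw = rng.random((m, n))
    probs = raw / raw.sum(axis=1, keepdims=True)
    want = roc_auc_score(truth, probs if n > 2 else probs[:, 1], multi_class="ovr", average="macro")
    assert multiclass_auc(truth, probs) == pytest.approx(want, abs=1e-10)


def test_auc_warns_and_excludes_absent_class():
    probs = np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1], [0.3, 0.6, 0.1], [0.6, 0.3, 0.1]])
    with pytest.warns(UserWarning, match="excluded"):
        macro, per_class = multiclass_auc([0, 1, 1, 0], probs, return_per_class=True)
    assert set(per_class) == {0, 1}


def test_report_serialization(tmp_path):
    cm, report = evaluate_predictions(["a", "b", "a"], ["a", "b", "b"], ["a", "b"])
    report.to_json(tmp_path / "m.json")
    report.to_csv(tmp_path / "m.csv")
    cm.to_csv(tmp_path / "cm.csv")
    import json, pandas as pd

    loaded = json.loads((tmp_path / "m.json").read_text())
    assert loaded["aggregate"]["accuracy"] == pytest.approx(2 / 3)
    assert "rows=true" in loaded["orientation"]
    df = pd.read_csv(tmp_path / "m.csv")
    assert list(df["class"]) == ["a", "b", "__aggregate__"]
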