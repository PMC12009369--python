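"""Metric suite: grouped probabilities, binary metrics, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ttdml import (BinaryTask, binary_metrics, calibration_curve, default_tasks,
                   ece, evaluate_model, group_probability)


# -- independent oracles -----------------------------------------------------

def brute_force_ece(probs, labels, n_bins=10):
    """Direct enumeration over equal-width bins."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    total = 0.0
    for b in range(n_bins):
        lo, hi = b / n_bins, (b + 1) / n_bins
        if b == n_bins - 1:
            sel = (probs >= lo) & (probs <= hi)
        else:
            sel = (probs >= lo) & (probs < hi)
        if not sel.any():
            continue
        total += (sel.sum() / len(probs)) * abs(probs[sel].mean()
                                                - labels[sel].mean())
    return total


def mann_whitney_auc(probs, labels):
    """Pair-counting AUC: concordant pairs + half the ties."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# -- grouped probabilities ---------------------------------------------------

def test_group_probability_examples():
    p = np.array([0.7, 0.1, 0.1, 0.1])
    assert group_probability(p, BinaryTask(30.0))[0] == pytest.approx(0.7)
    assert group_probability(p, BinaryTask(60.0))[0] == pytest.approx(0.8)
    uniform = np.full(4, 0.25)
    assert group_probability(uniform, BinaryTask(120.0))[0] == pytest.approx(0.75)


def test_task_threshold_must_be_bin_edge():
    with pytest.raises(ValueError):
        BinaryTask(45.0)


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=4, max_size=4))
@settings(max_examples=100, deadline=None)
def test_grouped_probabilities_nested(raw):
    """P(<30) <= P(<60) <= P(<120) for every probability vector."""
    raw = np.array(raw) + 1e-9
    p = raw / raw.sum()
    probs = [group_probability(p, BinaryTask(e))[0] for e in (30.0, 60.0, 120.0)]
    assert probs[0] <= probs[1] + 1e-12
    assert probs[1] <= probs[2] + 1e-12


# -- binary metrics ----------------------------------------------------------

def test_perfect_separation_scores_one():
    probs = np.array([0.9, 0.8, 0.2, 0.1])
    labels = np.array([1, 1, 0, 0])
    m = binary_metrics(probs, labels)
    for key in ("accuracy", "f1", "ppv", "npv", "roc_auc", "pr_auc"):
        assert m[key] == pytest.approx(1.0)


def test_auc_small_instances_by_pair_enumeration():
    # positives {0.9, 0.3} vs negatives {0.8, 0.1}: 3 concordant pairs of 4
    m = binary_metrics(np.array([0.9, 0.8, 0.3, 0.1]), np.array([1, 0, 1, 0]))
    assert m["roc_auc"] == pytest.approx(0.75)
    # positives {0.9, 0.3} vs negatives {0.8, 0.4}: 2 concordant of 4 -> 0.5
    m = binary_metrics(np.array([0.9, 0.8, 0.3, 0.4]), np.array([1, 0, 1, 0]))
    assert m["roc_auc"] == pytest.approx(0.5)


def test_random_probs_auc_near_half(rng):
    labels = rng.integers(0, 2, size=4000)
    probs = rng.random(4000)
    m = binary_metrics(probs, labels)
    assert abs(m["roc_auc"] - 0.5) < 0.03


def test_no_predicted_positives_reports_zero_ppv():
    m = binary_metrics(np.array([0.1, 0.2, 0.3]), np.array([1, 0, 1]))
    assert m["ppv"] == 0.0
    assert m["accuracy"] == pytest.approx(1 / 3)


def test_single_class_labels_flag_undefined_aucs():
    m = binary_metrics(np.array([0.2, 0.8]), np.array([1, 1]))
    assert np.isnan(m["roc_auc"]) and np.isnan(m["pr_auc"])


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        binary_metrics(np.array([0.1]), np.array([1, 0]))


def test_auc_matches_pair_counting_oracle(rng):
    """Trapezoidal/rank AUC equals Mann-Whitney pair counting, including
    with heavy ties, on every instance with n <= 50."""
    for _ in range(100):
        n = int(rng.integers(4, 51))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        probs = np.round(rng.random(n), 1)  # coarse grid forces ties
        m = binary_metrics(probs, labels)
        assert m["roc_auc"] == pytest.approx(mann_whitney_auc(probs, labels),
                                             abs=1e-12)


# -- calibration -------------------------------------------------------------

def test_ece_perfectly_confident_and_correct():
    assert ece(np.ones(5), np.ones(5)) == pytest.approx(0.0)


def test_ece_single_bin_formula():
    probs = np.full(10, 0.8)
    labels = np.array([1, 0] * 5)
    assert ece(probs, labels) == pytest.approx(0.3)


def test_ece_two_bin_hand_example():
    probs = np.array([0.05, 0.05, 0.05, 0.95, 0.95, 0.95])
    labels = np.array([0, 0, 1, 1, 1, 0])
    expected = 0.5 * abs(0.05 - 1 / 3) + 0.5 * abs(0.95 - 2 / 3)
    assert expected == pytest.approx(0.28333333333)
    assert ece(probs, labels) == pytest.approx(expected, abs=1e-12)
    assert brute_force_ece(probs, labels) == pytest.approx(expected, abs=1e-12)


def test_ece_matches_brute_force_oracle(rng):
    for _ in range(200):
        n = int(rng.integers(3, 120))
        probs = rng.random(n)
        labels = rng.integers(0, 2, size=n)
        assert ece(probs, labels) == pytest.approx(
            brute_force_ece(probs, labels), abs=1e-12)


def test_ece_rejects_out_of_range():
    with pytest.raises(ValueError):
        ece(np.array([1.2]), np.array([1]))


def test_calibration_curve_consistent_with_ece(rng):
    probs = rng.random(300)
    labels = rng.integers(0, 2, size=300)
    table = calibration_curve(probs, labels)
    recomputed = sum(r["count"] / 300 * abs(r["mean_confidence"]
                                            - r["empirical_frequency"])
                     for _, r in table.iterrows())
    assert recomputed == pytest.approx(ece(probs, labels), abs=1e-12)


def test_calibration_curve_single_bin():
    table = calibration_curve(np.full(4, 0.42), np.array([0, 1, 0, 1]))
    assert len(table) == 1
    assert table.iloc[0]["count"] == 4


def test_well_calibrated_draws_near_diagonal(rng):
    probs = rng.random(20000)
    labels = (rng.random(20000) < probs).astype(int)
    table = calibration_curve(probs, labels)
    gaps = (table["mean_confidence"] - table["empirical_frequency"]).abs()
    assert gaps.max() < 0.03


# -- full reports ------------------------------------------------------------

class _FixedPredictor:
    def __init__(self, probs):
        self._probs = np.asarray(probs)

    def predict_proba(self, patients):
        return self._probs[: len(patients)]


def test_uniform_random_predictor_accuracy_quarter(small_split, rng):
    """A uniform-random 4-way classifier has expected accuracy 0.25."""
    labels = rng.integers(0, 4, size=100_000)
    raw = rng.random((100_000, 4))
    preds = np.argmax(raw, axis=1)
    acc = float((preds == labels).mean())
    assert acc == pytest.approx(0.25, abs=0.01)


def test_oracle_predictions_score_perfectly(small_split):
    test = small_split["test"]
    probs = np.zeros((len(test), 4))
    probs[np.arange(len(test)), [p.label for p in test]] = 1.0
    report = evaluate_model(_FixedPredictor(probs), test)
    assert report.mean["accuracy4"] == pytest.approx(1.0)
    for task in ("lt30", "lt60", "lt120"):
        assert report.mean[f"roc_auc_{task}"] == pytest.approx(1.0)
    assert report.mean["ece"] == pytest.approx(0.0)


def test_report_schema_and_ranges(small_split, rng):
    test = small_split["test"]
    raw = rng.random((len(test), 4))
    probs = raw / raw.sum(axis=1, keepdims=True)
    report = evaluate_model(_FixedPredictor(probs), test,
                            model_name="random")
    d = report.to_dict()
    assert d["model"] == "random"
    assert d["n"] == len(test)
    for key, val in d["mean"].items():
        if np.isfinite(val):
            assert 0.0 <= val <= 1.0, key
    for task in ("lt30", "lt60", "lt120"):
        for metric in ("accuracy", "f1", "ppv", "npv", "roc_auc", "pr_auc",
                       "ece"):
            assert f"{metric}_{task}" in d["mean"]


def test_empty_test_cohort_rejected():
    with pytest.raises(ValueError):
        evaluate_model(_FixedPredictor(np.zeros((0, 4))), [])
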