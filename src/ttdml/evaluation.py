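"""The metric suite: 4-way accuracy, grouped binary tasks, calibration.

The four TTD class probabilities are collapsed into binary "grouped"
tasks (<30, <60, <120 minutes vs the rest) by summing the class
probabilities of all bins entirely below the threshold; binary decisions
use a 0.5 cut. Calibration is summarized by the expected calibration
error (ECE) over equal-width probability bins, and the calibration-curve
table behind a reliability diagram is exposed so the ECE can be recomputed
from it exactly.

Ensembles are reported as mean +/- sd across members, mirroring the
practice of training several models with different initializations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (accuracy_score, average_precision_score,
                             f1_score, roc_auc_score)

from .preprocessing import DEFAULT_BIN_EDGES, PreparedPatient


@dataclass(frozen=True)
class BinaryTask:
    """Positive class: TTD strictly below ``threshold_min`` minutes."""

    threshold_min: float
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES

    def __post_init__(self) -> None:
        if self.threshold_min not in self.bin_edges:
            raise ValueError(
                f"task threshold {self.threshold_min} must be one of the "
                f"label bin edges {self.bin_edges}")

    @property
    def name(self) -> str:
        return f"lt{int(self.threshold_min)}"

    def labels(self, ttd_minutes: np.ndarray) -> np.ndarray:
        return (np.asarray(ttd_minutes) < self.threshold_min).astype(int)


def default_tasks(bin_edges=DEFAULT_BIN_EDGES) -> list[BinaryTask]:
    return [BinaryTask(e, tuple(bin_edges)) for e in bin_edges]


def group_probability(probs: np.ndarray, task: BinaryTask) -> np.ndarray:
    """P(TTD < threshold) = sum of class probabilities below the threshold."""
    probs = np.atleast_2d(probs)
    n_below = task.bin_edges.index(task.threshold_min) + 1
    return probs[:, :n_below].sum(axis=1)


def binary_metrics(probs, labels, decision_threshold: float = 0.5) -> dict:
    """Accuracy, F1, PPV, NPV, ROC-AUC and PR-AUC for one binary task.

    Degenerate cases follow the reporting convention for rule-based
    predictors that never emit one of the classes: an undefined PPV or NPV
    is reported as 0.0. AUCs are NaN when only one class is present.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must have equal length")
    pred = (probs >= decision_threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    ppv = tp / (tp + fp) if (tp + fp) else 0.0
    npv = tn / (tn + fn) if (tn + fn) else 0.0
    both_classes = len(np.unique(labels)) == 2
    return {
        "accuracy": float(accuracy_score(labels, pred)),
        "f1": float(f1_score(labels, pred, zero_division=0)),
        "ppv": float(ppv),
        "npv": float(npv),
        "roc_auc": float(roc_auc_score(labels, probs)) if both_classes else float("nan"),
        "pr_auc": (float(average_precision_score(labels, probs))
                   if both_classes else float("nan")),
    }


def ece(probs, labels, n_bins: int = 10) -> float:
    """Expected calibration error over equal-width probability bins.

    ECE = sum_b (n_b / n) * |mean confidence_b - empirical frequency_b|,
    empty bins skipped. Probabilities of exactly 1.0 fall in the top bin.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    bins = np.minimum((probs * n_bins).astype(int), n_bins - 1)
    total = 0.0
    n = len(probs)
    for b in range(n_bins):
        in_bin = bins == b
        n_b = int(in_bin.sum())
        if n_b == 0:
            continue
        conf = probs[in_bin].mean()
        freq = labels[in_bin].mean()
        total += (n_b / n) * abs(conf - freq)
    return float(total)


def calibration_curve(probs, labels, n_bins: int = 10) -> pd.DataFrame:
    """Reliability-diagram table: per non-empty bin, the mean predicted
    probability, the empirical positive frequency and the count.

    Recomputing sum (count/n)*|confidence - frequency| over the rows
    reproduces :func:`ece` exactly.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    bins = np.minimum((probs * n_bins).astype(int), n_bins - 1)
    rows = []
    for b in range(n_bins):
        in_bin = bins == b
        if not in_bin.any():
            continue
        rows.append({
            "bin": b,
            "bin_lo": b / n_bins,
            "bin_hi": (b + 1) / n_bins,
            "mean_confidence": float(probs[in_bin].mean()),
            "empirical_frequency": float(labels[in_bin].mean()),
            "count": int(in_bin.sum()),
        })
    return pd.DataFrame(rows)


@dataclass
class MetricReport:
    """Per-member and aggregated metrics for one model (or ensemble)."""

    model_name: str
    n: int
    tasks: list[str]
    per_member: list[dict]
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = self.per_member[0].keys()
        for key in keys:
            vals = np.array([m[key] for m in self.per_member], dtype=float)
            ok = np.isfinite(vals)
            self.mean[key] = float(vals[ok].mean()) if ok.any() else float("nan")
            self.sd[key] = float(vals[ok].std()) if ok.any() else float("nan")

    def to_dict(self) -> dict:
        return {"model": self.model_name, "n": self.n, "tasks": self.tasks,
                "per_member": self.per_member, "mean": self.mean, "sd": self.sd}


def _member_metrics(probs: np.ndarray, labels4: np.ndarray,
                    ttd: np.ndarray, tasks: list[BinaryTask],
                    n_bins: int = 10) -> dict:
    out = {"accuracy4": float(accuracy_score(labels4, np.argmax(probs, axis=1)))}
    for task in tasks:
        p = group_probability(probs, task)
        y = task.labels(ttd)
        bm = binary_metrics(p, y)
        for key, val in bm.items():
            out[f"{key}_{task.name}"] = val
        out[f"ece_{task.name}"] = ece(p, y, n_bins)
    # headline calibration: the <30-minute task
    out["ece"] = out.get("ece_lt30", out[f"ece_{tasks[0].name}"])
    return out


def evaluate_model(model_or_ensemble, test_patients: list[PreparedPatient],
                   tasks: list[BinaryTask] | None = None,
                   bin_edges=DEFAULT_BIN_EDGES,
                   model_name: str = "model",
                   n_calibration_bins: int = 10) -> MetricReport:
    """Evaluate a model (anything with ``predict_proba``) or a list of them.

    4-way accuracy is argmax accuracy; binary tasks use grouped
    probabilities; each member of an ensemble is scored separately and the
    report carries mean +/- sd.
    """
    if not test_patients:
        raise ValueError("empty test cohort")
    members = (model_or_ensemble if isinstance(model_or_ensemble, (list, tuple))
               else [model_or_ensemble])
    tasks = tasks or default_tasks(bin_edges)
    labels4 = np.array([p.label for p in test_patients])
    ttd = np.array([p.ttd_minutes for p in test_patients])
    per_member = []
    for member in members:
        probs = member.predict_proba(test_patients)
        per_member.append(_member_metrics(probs, labels4, ttd, tasks,
                                          n_calibration_bins))
    return MetricReport(model_name=model_name, n=len(test_patients),
                        tasks=[t.name for t in tasks], per_member=per_member)
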